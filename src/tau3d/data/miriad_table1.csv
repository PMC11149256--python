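id,diagnosis,frontal,occipital,parietal,temporal
1,AD,67.4,31.8,59.7,36.6
2,AD,67.1,26.5,59.3,37.7
3,AD,67.7,30.1,54.5,38.0
4,Control,66.5,28.6,56.1,39.9
5,AD,63.8,35.0,55.9,36.6
6,Control,70.2,38.9,58.9,35.9
7,Control,68.5,33.3,59.0,43.1
8,AD,62.8,35.9,57.7,34.1
9,Control,75.3,34.8,60.7,40.2
10,AD,72.8,30.7,59.1,35.1
11,AD,68.6,30.2,54.8,36.4
12,AD,75.8,35.8,62.5,39.2
13,AD,67.2,30.1,57.0,38.7
14,AD,63.9,32.2,45.2,35.9
15,AD,67.0,32.0,57.1,36.7
16,AD,62.2,30.4,47.0,32.6
17,AD,69.1,34.6,64.2,40.5
18,AD,74.7,31.0,63.7,42.9
19,AD,58.2,32.5,55.5,38.4
20,AD,72.3,32.5,62.9,39.4
21,AD,70.4,35.2,62.0,39.9
22,AD,59.2,32.1,54.4,34.3
23,Control,73.3,32.2,63.1,39.9
24,Control,77.0,34.4,62.1,42.4
25,AD,77.3,33.7,63.4,40.8
26,Control,64.6,36.9,64.0,39.8
27,AD,63.4,35.4,60.4,36.4
28,Control,63.4,35.4,60.4,36.4
29,Control,63.4,35.4,60.4,36.4
30,AD,69.2,33.7,61.6,40.7
31,AD,53.8,39.8,61.0,30.9
32,Control,66.6,34.2,68.5,35.9
33,AD,69.9,33.6,63.0,38.2
34,Control,74.4,34.7,59.8,47.8
35,Control,69.2,34.7,65.5,43.7
36,Control,76.2,41.3,70.0,44.7
37,Control,72.4,36.8,64.3,47.4
38,AD,78.9,36.1,63.4,45.0
39,Control,70.9,38.5,67.7,41.2
40,AD,70.9,38.5,67.7,41.2
41,AD,52.6,29.8,45.8,34.9
42,Control,65.8,32.1,61.4,50.1
43,AD,68.4,34.5,55.5,46.9
44,AD,68.4,34.5,55.5,46.9
45,Control,86.7,35.1,73.2,49.8
46,AD,69.9,41.5,65.7,47.0
47,Control,70.6,32.3,62.4,47.8
48,AD,63.0,36.6,62.1,39.8
49,Control,67.0,37.5,68.8,45.2
50,AD,69.0,34.1,63.0,45.1
51,Control,70.7,33.6,62.5,45.9
52,Control,74.0,32.4,62.2,46.0
53,Control,69.2,36.7,64.1,42.6
54,AD,59.4,35.1,58.3,39.6
55,Control,74.6,33.3,58.7,41.9
56,AD,74.6,33.3,58.7,41.9
57,AD,61.2,31.3,55.1,40.0
58,AD,67.1,30.1,53.9,39.6
59,AD,57.3,27.4,45.5,35.9
60,AD,70.4,32.9,63.3,46.3
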