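# tau3d — slope-chain-code tortuosity for 3D voxelized objects

`tau3d` measures the tortuosity (the amount of twisting and turning) of 3D
objects given as binary voxel volumes — brain structures segmented from MRI,
tumors, bones, any occupancy grid. Unlike the classical arc/chord ratio
τ = C/L, which cannot tell a gently curved path from a jagged one of equal
length, the Slope Chain Code (SCC) tortuosity accumulates every change of
direction along a curve:

τ = Σₙ |aₙ|,  aₙ ∈ (−1, 1),

where aₙ is the turning angle between consecutive straight segments,
normalized by π. For every simple convex closed curve τ = 2 exactly. The 3D
measure slices the volume along the three grid axes, filters the
stair-stepping artifact of voxelization from each boundary contour
(downsampling by a factor of 10, then digital-straight-segment merging under
a narrowest-strip criterion), and aggregates

τ₃D = (Σᵢ Σₙ |xₙᵢ|)/S_X + (Σⱼ Σₘ |yₘⱼ|)/S_Y + (Σₖ Σₗ |zₗₖ|)/S_Z,

with S_X, S_Y, S_Z the number of object-intersecting slices per axis. For
convex closed surfaces τ₃D = 6, which calibrates the measure: digitized
spheres across radii 10–70 voxels stay within ±1 of 6 at the default
settings. See `docs/methods.md` for the full method description.

The package also bundles the published per-subject lobe tortuosities of 60
MIRIAD subjects (37 Alzheimer's disease, 23 controls) and reproduces the
group comparison (Wilcoxon rank-sum per lobe, medians per group).

## Worked example

```python
import numpy as np
from tau3d import (FilterParams, make_cube, make_sphere, make_bumpy_sphere,
                   tortuosity_3d, closing_experiment)

print(tortuosity_3d(make_cube(41)).tau3d)      # 6.0   (convex solid)
print(tortuosity_3d(make_sphere(30)).tau3d)    # 6.0   (digitized sphere)

bumpy = make_bumpy_sphere(25, bump_amplitude=5, bump_frequency=6)
print(round(tortuosity_3d(bumpy).tau3d, 3))    # 21.257 (gyrified stand-in)

for r, tau in closing_experiment(bumpy, [2, 4, 6, 8]):
    print(r, round(tau, 3))
# 0 21.257
# 2 18.091
# 4 15.315
# 6 12.975
# 8 12.405
```

The cube and sphere hit the convex-surface value 6 exactly; the bumpy sphere
is far more tortuous, and morphological closing with growing ball radii
smooths surface detail away, driving τ₃D monotonically down — the behaviour
expected of a shape-complexity measure under smoothing.

The same from the shell:

```bash
tau3d make-shape sphere --radius 30 -o sphere.nii.gz
tau3d compute sphere.nii.gz --json result.json   # tau3d = 6
tau3d validate-spheres --radii 10:80:10 --angles 0:360:45
tau3d cohort                                     # rank-sum report per lobe
```

`tau3d compute` emits a JSON result with the per-slice breakdown
(`{tau3d, axis_means: {X, Y, Z}, S: {X, Y, Z}, params, per_slice: [...]}`),
so every aggregate can be audited.

Cohort statistics on the bundled table:

```python
from tau3d import load_table1, cohort_report
print(cohort_report(load_table1())[["region", "z", "p",
      "median_AD_rounded", "median_Control_rounded"]])
#       region         z         p  median_AD_rounded  median_Control_rounded
# 0    frontal  2.220262  0.026401                 68                      71
# 1  occipital  2.174822  0.029643                 33                      35
# 2   parietal  3.140259  0.001688                 59                      62
# 3   temporal  2.981289  0.002870                 39                      43
```

All four lobes differ significantly between groups (p < 0.05), with controls
ranking higher — reduced folding complexity in the disease group.

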