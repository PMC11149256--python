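# Methods

## The measure

`tau3d` quantifies how much the surface of a voxelized 3D object twists and
turns. It is a slice-based extension of the Slope Chain Code (SCC) tortuosity
for 2D curves.

For a polygonal curve, the SCC encodes at each vertex the turning angle
between the incoming and outgoing straight segments, normalized by π so each
element lies in the open interval (−1, 1). The 2D tortuosity of the curve is
the sum of absolute chain elements,

τ = Σₙ |aₙ|.

For any simple convex closed polygon the total absolute turning is exactly
2π, so τ = 2 regardless of vertex count or scale. This identity is the
anchor of everything below.

The 3D measure slices the binary volume perpendicular to each of the three
grid axes, computes the SCC tortuosity of every (filtered) boundary contour
in every slice that intersects the object, and aggregates

τ₃D = (Σ slice τ in X)/S_X + (Σ slice τ in Y)/S_Y + (Σ slice τ in Z)/S_Z,

where S_X, S_Y, S_Z count the foreground-intersecting slices per axis. Every
cross-section of a convex solid is convex, so τ₃D of a convex closed surface
is 6 — the theoretical reference used for validation.

**Slice-count convention.** S counts only slices that intersect the object,
not all slices of the array. Counting empty slices would make τ₃D depend on
how much empty padding surrounds the object and would destroy the
convex-surface identity; with foreground-only counting, padding invariance is
exact (asserted in tests). This is a deliberate resolution of an ambiguity in
the aggregation's verbal description, and it should be kept in mind when
comparing absolute values against other implementations.

## Pipeline

1. **Binarize / load.** Volumes are boolean grids indexed (x, y, z); voxel
   (i, j, k) occupies the unit cube [i, i+1)×[j, j+1)×[k, k+1). Default
   binarization threshold on raw intensities is 0.5. NIfTI orientation
   metadata is ignored: the measure is only comparable within one grid
   convention, and isotropic voxels are assumed throughout.
2. **Trace contours.** Boundaries are traced on the inter-pixel crack
   lattice, giving closed 4-connected loops on integer pixel corners. This
   makes the stair-stepping artifact explicit (unit steps, 90° turns) and
   gives a single pixel a well-defined closed curve of 4 vertices.
   Foreground is 8-connected, background 4-connected (Jordan-consistent). At
   a checkerboard corner — two foreground pixels meeting only diagonally —
   the trace turns right and passes through the corner twice, keeping the
   component on one loop; this pinch is the only situation where a vertex
   repeats, and it cannot occur on the smooth volumetric objects the measure
   targets. Outer loops are counterclockwise, holes clockwise, and loops
   start at their lexicographically smallest vertex, so outputs are
   byte-reproducible. Hole contours are traced and contribute to slice
   tortuosity by default (`include_holes`), since a hollow structure's shape
   complexity lives partly in its cavities; the switch exists because the
   convention is not universal.
3. **Filter the stair-stepping artifact**, in two stages, in this order:
   - *Downsampling*: keep every `dsf`-th contour vertex (default 10). Small
     contours reduce the effective factor so at least `min_vertices`
     (default 3) survive.
   - *DSS simplification*: merge maximal runs of surviving vertices that fit
     a digital straight segment. Because downsampled vertices are no longer
     lattice-adjacent, arithmetic DSS recognition does not apply; a run
     counts as straight while the *narrowest enclosing strip* of its points
     — the width of their convex hull, minimized over orientation — does not
     exceed `strip_width` (default 1.0 voxel). Runs are grown greedily and
     the retained vertices are the run endpoints. Closed loops are seeded at
     the vertex farthest from the loop centroid (a corner-like point, so the
     seam never splits a genuine straight run; lexicographic tie-break), and
     after the loop closes the runs on both sides of the seed are merged if
     their union still fits one strip. If simplification would leave fewer
     than `min_vertices` vertices on a closed loop, the unsimplified
     polyline is kept.
4. **Encode and sum.** Chain elements are computed with atan2(cross, dot) of
   consecutive segment vectors, so each element is guaranteed in [−1, 1];
   signs (positive = counterclockwise) are retained for diagnostics but only
   absolute values enter τ. An exact reversal (|a| = 1, excluded from the
   open interval by definition) is resolved by deleting the apex vertex and
   recomputing, which keeps the chain honestly inside (−1, 1) instead of
   clamping. Closed chains have one element per vertex (cyclic); open chains
   N−2. The cyclic convention is forced by the τ = 2 convex identity.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `dsf` | 10 | vertices | downsampling stride; balances artifact removal vs. morphological detail. |
| `strip_width` | 1.0 | voxels | DSS strip tolerance; 1 voxel is the natural scale of the digitization noise the filter removes. |
| `min_vertices` | 3 | vertices | smallest representable closed loop. |
| `auto_dsf` | off | — | scales dsf with min bounding-box extent / 14; a fixed factor under-filters very large objects, but the fixed factor is the reference behaviour. |
| `include_holes` | on | — | whether inner contours contribute. |

## Validation

- **Convex identities.** τ of random convex polygons is 2 to 1e−9; τ₃D of a
  voxelized cube (side 41) and of a single voxel is 6 to 1e−6.
- **Spheres.** Digitized spheres are generated across radii 10–70 voxels and
  8 "generation angles". A rotation-invariant solid cannot meaningfully be
  rotated, so the angle is mapped to a sub-voxel center offset
  (frac(angle/360 · mᵢ) with fixed irrational multipliers: golden ratio, √2,
  √3), which samples rasterization phase exactly as rotating the generating
  sphere against the grid would. The absolute error Δ = |τ₃D − 6| is below 1
  across the whole sweep at the default parameters; in this implementation
  the measured maximum is 0 — every sphere slice filters to a convex
  polygon — comfortably inside the published ±1 band.
- **Smoothing monotonicity.** A "bumpy sphere" (radius 25, sinusoidal radial
  perturbation of amplitude 5, angular frequency 6 — a stand-in for a
  gyrified cortical surface) has τ₃D ≈ 21, and morphological closing with
  discrete balls of radius 2, 4, 6, 8 produces a monotonically decreasing
  τ₃D sequence (≈ 21.3 → 18.1 → 15.3 → 13.0 → 12.4), while closing leaves a
  plain sphere's τ₃D unchanged. Closing is computed on an internally padded
  copy so the structuring element never truncates at the array border.

### What the synthetic shapes do and do not show

The generators are deterministic (no RNG anywhere in the pipeline) and cover
convexity, sub-voxel phase, cavities and smooth non-convexity. They do not
emulate anisotropic voxels, intensity noise, segmentation error, or the
branching topology of real cortical surfaces; passing these suites shows the
measure and its filter behave as designed on clean digitized geometry, not
that any particular clinical preprocessing yields comparable values.

## Cohort statistics

The package bundles a verbatim transcription of the published per-subject
τ₃D values for four brain lobes of 60 MIRIAD subjects (37 Alzheimer's
disease, 23 controls) and reproduces the group comparison: Wilcoxon rank-sum
(Mann–Whitney) per lobe with midranks for ties, tie-corrected variance,
normal approximation, no continuity correction; z is signed so positive
means controls rank higher. Medians are reported raw and integer-rounded
(the publication's style); standard deviations use the sample (n−1)
convention.

Two data caveats, surfaced rather than "fixed":

- **Column swap.** The source's in-text medians for the parietal and
  occipital lobes match the *other* column of its per-subject table (e.g.
  "parietal M = 33" matches the occipital column). The bundled fixture
  follows the table's column headers verbatim; the z-to-region mapping for
  those two lobes inherits the ambiguity.
- **Residual z discrepancy.** From the printed (1-decimal) per-subject
  values, the frontal z is 2.220 under every standard rank-sum variant
  (2.213 with continuity correction; exact permutation gives the same
  2.220), whereas the source prints 2.190. All four lobes deviate by
  0.015–0.03 in mixed directions, consistent with the original z-values
  having been computed on unrounded τ₃D values. The implementation does not
  switch variants to chase the printed number; the computed values are
  frontal 2.220, occipital 2.175, parietal 3.140, temporal 2.981.

## Numerical choices and known limitations

- Strip-width comparisons are ≤ on exact geometric widths; all contour
  coordinates are integers, so run boundaries are not sensitive to floating
  noise at the default settings.
- Greedy DSS depends on traversal direction. Axis permutation of a volume
  transposes two of the three slice families, which reverses contour
  traversal; τ₃D is therefore exactly permutation-invariant on convex solids
  (every slice filters to τ = 2 regardless of direction) but only
  approximately (a few percent) on strongly non-convex objects.
- Slices whose contours all collapse below `min_vertices` contribute 0 but
  still count in S (the denominator stays purely geometric).
- Objects touching the array border are padded by one empty layer, not
  rejected, so smoothing experiments remain comparable.
- Problem sizes in the shipped experiments (spheres to radius 70, bumpy
  sphere radius 25) were chosen to exercise the full published radius band
  while keeping each experiment in the minutes range on one CPU.
- Age/sex-adjusted regressions and the central-sulcus comparison from the
  source study are not implemented: the required covariates and per-subject
  sulcus values are not published, so they could not be reproduced or tested
  honestly. The rank-sum machinery accepts user-supplied two-group tables so
  the same tests can be run on user-computed structures.
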