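"""Stair-stepping filter: contour downsampling + digital-straight-segment fit.

A crack contour of a digitized oblique boundary consists entirely of unit
steps and 90-degree turns, so its raw slope chain wildly overstates the
object's true tortuosity.  The filter removes this artifact in two stages,
in this order:

1. **Downsampling** — keep every ``dsf``-th contour vertex (default 10).
2. **DSS simplification** — merge maximal runs of the surviving vertices that
   fit a digital straight segment, recognized by the narrowest-strip
   criterion: a run is straight while the minimal-width enclosing strip of
   its points (over all orientations, i.e. the width of their convex hull)
   does not exceed ``strip_width``.

Since downsampled vertices are no longer lattice-adjacent, the classical
arithmetic DSS recognition does not apply verbatim; the strip criterion is
evaluated geometrically on real coordinates, with the strip width exposed as
a parameter (default 1.0 voxel).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .contours import Contour

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Tunable parameters of the stair-stepping filter.

    dsf
        Downsampling factor: stride between kept contour vertices.
    strip_width
        Maximal width (voxel units) of the enclosing strip for a run of
        points to count as one digital straight segment.
    min_vertices
        Minimum vertex count of a closed filtered polyline; downsampling
        reduces its effective factor, and DSS falls back to the unsimplified
        polyline, rather than go below it.
    auto_dsf
        Scale dsf with object size (min bounding-box extent / 14) instead of
        using the fixed factor; off by default.
    include_holes
        Whether inner (hole) contours contribute to slice tortuosity.
    """

    dsf: int = 10
    strip_width: float = 1.0
    min_vertices: int = 3
    auto_dsf: bool = False
    include_holes: bool = True

    def __post_init__(self) -> None:
        if self.dsf < 1:
            raise ValueError("downsampling factor must be >= 1")
        if self.strip_width <= 0:
            raise ValueError("strip width must be positive")
        if self.min_vertices < 3:
            raise ValueError("min_vertices must be >= 3")


@dataclass
class Polyline:
    """A vertex sequence: a contour after downsampling and/or DSS filtering."""

    vertices: np.ndarray = field(repr=False)
    closed: bool = True
    source: Optional[Contour] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)

    def __len__(self) -> int:
        return len(self.vertices)


def _collapse_duplicates(pts: np.ndarray, closed: bool) -> np.ndarray:
    """Drop consecutive repeated points (cyclically for closed sequences)."""
    if len(pts) < 2:
        return pts
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    if not closed:
        keep[0] = True
    return pts[keep]


def downsample(c: Contour, params: FilterParams) -> Polyline:
    """Keep contour vertices at cyclic indices 0, dsf, 2*dsf, ...

    If fewer than ``min_vertices`` would survive, the effective factor is
    reduced to ``max(1, N // min_vertices)`` so small contours keep a
    representable loop.
    """
    verts = c.vertices
    n = len(verts)
    eff = params.dsf
    if math.ceil(n / eff) < params.min_vertices:
        eff = max(1, n // params.min_vertices)
        logger.debug("downsample: contour of %d vertices, dsf %d -> effective %d",
                     n, params.dsf, eff)
    pts = verts[::eff].astype(float)
    pts = _collapse_duplicates(pts, closed=True)
    return Polyline(vertices=pts, closed=True, source=c)


def min_strip_width(points: np.ndarray) -> float:
    """Width of the narrowest strip (any orientation) enclosing ``points``.

    Equals the width of the convex hull: the minimum over hull edges of the
    largest perpendicular distance from the edge line to any point.  Collinear
    point sets have width 0.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) <= 2:
        return 0.0
    hull = _convex_hull(pts)
    if len(hull) <= 2:
        return 0.0
    best = math.inf
    h = np.asarray(hull)
    for i in range(len(h)):
        p = h[i]
        q = h[(i + 1) % len(h)]
        d = q - p
        norm = math.hypot(d[0], d[1])
        if norm == 0:
            continue
        dist = np.abs((h[:, 0] - p[0]) * d[1] - (h[:, 1] - p[1]) * d[0]) / norm
        best = min(best, float(dist.max()))
    return best


def _convex_hull(pts: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain on unique, lexicographically sorted points."""
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    if len(pts) <= 2:
        return pts

    def build(seq):
        out: list[np.ndarray] = []
        for p in seq:
            while len(out) >= 2:
                a, b = out[-2], out[-1]
                if (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0]) <= 0:
                    out.pop()
                else:
                    break
            out.append(p)
        return out

    lower = build(pts)
    upper = build(pts[::-1])
    return np.array(lower[:-1] + upper[:-1])


def _greedy_runs(pts: np.ndarray, strip_width: float) -> list[int]:
    """Greedy maximal-run split of an open point sequence.

    Returns the indices of run endpoints (always includes 0 and len-1): each
    run ``pts[s..e]`` fits a strip of width <= strip_width and extending it by
    one more point would not.
    """
    n = len(pts)
    retained = [0]
    s = 0
    while s < n - 1:
        e = s + 1
        while e + 1 < n and min_strip_width(pts[s:e + 2]) <= strip_width:
            e += 1
        retained.append(e)
        s = e
    return retained


def dss_simplify(p: Polyline, params: FilterParams) -> Polyline:
    """Reduce a polyline to the endpoints of maximal digital straight segments.

    Closed polylines are handled cyclically: simplification starts from the
    vertex farthest from the loop centroid (a corner-like point, so the seam
    does not split a genuine straight run), and after closing the loop the
    last and first runs are merged when their union still fits one strip.
    Falls back to the input polyline when fewer than ``min_vertices`` vertices
    would remain on a closed loop.
    """
    pts = _collapse_duplicates(np.asarray(p.vertices, dtype=float), p.closed)
    n = len(pts)
    if not p.closed:
        if n <= 2:
            return Polyline(pts, closed=False, source=p.source)
        idx = _greedy_runs(pts, params.strip_width)
        return Polyline(pts[idx], closed=False, source=p.source)

    if n <= params.min_vertices:
        return Polyline(pts, closed=True, source=p.source)

    centroid = pts.mean(axis=0)
    d2 = ((pts - centroid) ** 2).sum(axis=1)
    # farthest-from-centroid seed; lexicographic tie-break for determinism
    order = np.lexsort((pts[:, 1], pts[:, 0], -d2))
    seed = int(order[0])
    rot = np.roll(pts, -seed, axis=0)
    ext = np.vstack([rot, rot[:1]])
    idx = _greedy_runs(ext, params.strip_width)
    retained = idx[:-1]  # drop the duplicated seed at the end

    if len(retained) >= 3 and len(idx) >= 3:
        # seam merge: drop the seed if the runs on both sides of it fuse
        last_start = idx[-2]
        first_end = idx[1]
        seam = np.vstack([ext[last_start:len(ext) - 1], rot[:first_end + 1]])
        if min_strip_width(seam) <= params.strip_width:
            retained = retained[1:]

    if len(retained) < params.min_vertices:
        logger.debug("dss_simplify: loop collapsed below %d vertices; keeping input",
                     params.min_vertices)
        return Polyline(pts, closed=True, source=p.source)
    return Polyline(rot[retained], closed=True, source=p.source)


def filter_contour(c: Contour, params: FilterParams) -> Polyline:
    """Full stair-stepping filter: downsample first, then DSS-simplify."""
    return dss_simplify(downsample(c, params), params)


def params_for_volume(params: FilterParams, grid: np.ndarray) -> FilterParams:
    """Resolve auto_dsf against an object's bounding box (no-op otherwise)."""
    if not params.auto_dsf:
        return params
    idx = np.nonzero(grid)
    extents = [int(a.max() - a.min()) + 1 for a in idx]
    dsf = max(1, round(min(extents) / 14))
    logger.debug("auto_dsf: bounding box %s -> dsf %d", extents, dsf)
    return replace(params, dsf=dsf, auto_dsf=False)
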