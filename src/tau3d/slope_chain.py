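"""Slope Chain Code: turning-angle encoding of a polyline and 2D tortuosity.

Each chain element is the signed turning angle at a vertex between the
incoming and outgoing straight segments, normalized by pi so it lies in the
open interval (-1, 1).  This is the discrete curvature of the polygonal curve
at that vertex.  2D tortuosity is the sum of absolute chain elements; for any
simple convex closed polygon the total absolute turning is exactly 2*pi, so
its tortuosity is exactly 2 — the identity that anchors the validation of the
3D measure.

Exact reversals (turning angle of +/- pi, normalized value 1) fall outside
the open interval; they are resolved by deleting the apex vertex and
recomputing, which keeps the chain honestly inside (-1, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chain_filter import FilterParams, Polyline, _collapse_duplicates, filter_contour
from .contours import Contour

logger = logging.getLogger(__name__)

_REVERSAL_ATOL = 1e-12


class ChainUndefinedError(ValueError):
    """Raised when a polyline has too few segments to define a slope chain."""


@dataclass
class SlopeChain:
    """Ordered normalized slope changes of a polyline.

    For a closed polyline of N vertices there are N elements (one turn per
    vertex, cyclically); for an open polyline of N vertices, N - 2.
    """

    elements: np.ndarray = field(repr=False)
    closed: bool = True

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)

    def __len__(self) -> int:
        return len(self.elements)


def _turning_angles(verts: np.ndarray, closed: bool) -> np.ndarray:
    """Signed turning angle (units of pi) at each interior/cyclic vertex."""
    if closed:
        seg = np.roll(verts, -1, axis=0) - verts  # seg[i]: vertex i -> i+1
        inc = np.roll(seg, 1, axis=0)             # incoming at vertex i
        out = seg
    else:
        seg = np.diff(verts, axis=0)
        inc = seg[:-1]
        out = seg[1:]
    cross = inc[:, 0] * out[:, 1] - inc[:, 1] * out[:, 0]
    dot = inc[:, 0] * out[:, 0] + inc[:, 1] * out[:, 1]
    return np.arctan2(cross, dot) / np.pi


def slope_changes(p: Polyline) -> SlopeChain:
    """Encode a polyline as its Slope Chain Code.

    Requires >= 3 vertices (closed) or >= 2 segments (open).  Apexes of exact
    reversals are deleted and the chain recomputed.
    """
    verts = _collapse_duplicates(np.asarray(p.vertices, dtype=float), p.closed)
    for _ in range(len(verts)):
        n = len(verts)
        if (p.closed and n < 3) or (not p.closed and n < 3):
            raise ChainUndefinedError("chain undefined: need at least 2 segments")
        a = _turning_angles(verts, p.closed)
        reversal = np.isclose(np.abs(a), 1.0, atol=_REVERSAL_ATOL)
        if not reversal.any():
            return SlopeChain(elements=a, closed=p.closed)
        # delete apex vertices of exact reversals and recompute
        logger.debug("slope_changes: deleting %d reversal apex(es)", int(reversal.sum()))
        if p.closed:
            keep = ~reversal
        else:
            keep = np.ones(n, dtype=bool)
            keep[1:-1] = ~reversal
        verts = _collapse_duplicates(verts[keep], p.closed)
    raise ChainUndefinedError("chain undefined: polyline degenerates to reversals")


def tortuosity_2d(chain: SlopeChain) -> float:
    """Sum of absolute chain elements — the SCC tortuosity of the curve."""
    return float(np.abs(chain.elements).sum())


def polyline_tortuosity(p: Polyline) -> float:
    """Convenience: tortuosity of a polyline via its slope chain."""
    return tortuosity_2d(slope_changes(p))


def slice_tortuosity(contours: list[Contour], params: FilterParams) -> float:
    """Total tortuosity of one slice: sum over its (filtered) contours.

    Hole contours are included or skipped per ``params.include_holes``.
    Contours whose filtered polyline cannot define a chain contribute 0.
    An empty contour list yields 0.
    """
    total = 0.0
    for c in contours:
        if not params.include_holes and not c.is_outer:
            continue
        poly = filter_contour(c, params)
        try:
            total += tortuosity_2d(slope_changes(poly))
        except ChainUndefinedError:
            logger.debug("slice_tortuosity: degenerate contour on %s slice %d skipped",
                         c.axis, c.slice_index)
    return total
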