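"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct enumeration or O(n^2)/O(2^n)
computation — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def fill_from_loops(loops, shape) -> np.ndarray:
    """Even-odd rasterization of closed crack loops into a pixel mask.

    Pixel (i, j) is foreground iff a horizontal ray from (-inf, j+0.5) to its
    center crosses an odd number of vertical crack edges.
    """
    mask = np.zeros(shape, dtype=bool)
    vertical = []
    for verts in loops:
        v = np.asarray(verts)
        nxt = np.roll(v, -1, axis=0)
        for (x0, y0), (x1, y1) in zip(v, nxt):
            if x0 == x1:  # vertical edge between (x0, min(y)) and (x0, min(y)+1)
                vertical.append((x0, min(y0, y1)))
    for i in range(shape[0]):
        for j in range(shape[1]):
            crossings = sum(1 for (x, y) in vertical if y == j and x <= i)
            mask[i, j] = crossings % 2 == 1
    return mask


def brute_strip_width(points) -> float:
    """Minimal enclosing strip width by testing every pair direction.

    The optimal strip is flush with a convex-hull edge, so the minimum over
    all point-pair directions of the projection spread onto the pair's normal
    equals the true minimal width.
    """
    pts = np.asarray(points, dtype=float)
    uniq = np.unique(pts, axis=0)
    if len(uniq) <= 2:
        return 0.0
    best = math.inf
    for a, b in itertools.combinations(uniq, 2):
        d = b - a
        norm = math.hypot(d[0], d[1])
        if norm == 0:
            continue
        n = np.array([-d[1], d[0]]) / norm
        proj = pts @ n
        best = min(best, float(proj.max() - proj.min()))
    return best


def brute_dilate(grid: np.ndarray, offsets) -> np.ndarray:
    out = np.zeros_like(grid)
    nx, ny, nz = grid.shape
    for i, j, k in zip(*np.nonzero(grid)):
        for dx, dy, dz in offsets:
            x, y, z = i + dx, j + dy, k + dz
            if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                out[x, y, z] = True
    return out


def brute_erode(grid: np.ndarray, offsets) -> np.ndarray:
    out = np.zeros_like(grid)
    nx, ny, nz = grid.shape
    for i, j, k in zip(*np.nonzero(grid)):
        ok = True
        for dx, dy, dz in offsets:
            x, y, z = i + dx, j + dy, k + dz
            if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz and grid[x, y, z]):
                ok = False
                break
        out[i, j, k] = ok
    return out


def ball_offsets(radius: int):
    r = int(radius)
    return [
        (dx, dy, dz)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dz in range(-r, r + 1)
        if dx * dx + dy * dy + dz * dz <= radius * radius
    ]


def brute_closing(grid: np.ndarray, radius: int) -> np.ndarray:
    """Set-based closing on a grid padded so dilation is never truncated."""
    pad = radius + 1
    padded = np.pad(grid, pad)
    offs = ball_offsets(radius)
    closed = brute_erode(brute_dilate(padded, offs), offs)
    return closed[pad:-pad, pad:-pad, pad:-pad]


def exact_ranksum_moments(pooled, n_b: int):
    """Exact mean and variance of the Mann-Whitney U of group B by enumerating
    every assignment of ``n_b`` of the pooled values to group B."""
    pooled = np.asarray(pooled, dtype=float)
    n = len(pooled)
    # midranks computed from scratch
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    us = []
    for combo in itertools.combinations(range(n), n_b):
        w = ranks[list(combo)].sum()
        us.append(w - n_b * (n_b + 1) / 2)
    us = np.asarray(us)
    return float(us.mean()), float(us.var())


def exact_ranksum_pvalue(a, b) -> float:
    """Exact two-sided p: probability of a |U - mean| at least as large."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    n_b = len(b)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    sv = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    obs = ranks[len(a):].sum()
    ws = [ranks[list(c)].sum() for c in itertools.combinations(range(n), n_b)]
    ws = np.asarray(ws)
    mean = ws.mean()
    return float(np.mean(np.abs(ws - mean) >= abs(obs - mean) - 1e-12))
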