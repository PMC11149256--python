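"""Synthetic voxelized test objects: spheres, cubes, bumpy spheres.

These are the fixtures for validating the tortuosity pipeline.  A digitized
sphere is the canonical convex closed surface (expected tau3d = 6); the
"generation angle" of a sphere is mapped to a deterministic sub-voxel offset
of the sphere center, which exercises the rasterization phase the same way
rotating the generating sphere against the grid would, without needing a
rotation pipeline.  All generators are deterministic — no randomness anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volumes import BinaryVolume

# Fixed irrational multipliers spreading the angle sweep over sub-voxel phase.
_PHASE_MULTIPLIERS = ((1.0 + math.sqrt(5.0)) / 2.0, math.sqrt(2.0), math.sqrt(3.0))


@dataclass(frozen=True)
class SphereSpec:
    """A digitized sphere: radius in voxels plus a generation angle.

    The angle (degrees, [0, 360)) determines a sub-voxel center offset in
    [0, 1)^3 via fixed irrational multipliers, so distinct angles sample
    distinct rasterization phases.
    """

    radius: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("sphere radius must be >= 1 voxel")

    @property
    def center_offset(self) -> tuple[float, float, float]:
        if self.angle == 0.0:
            return (0.0, 0.0, 0.0)
        t = self.angle / 360.0
        return tuple(math.modf(t * m)[0] for m in _PHASE_MULTIPLIERS)  # type: ignore[return-value]


def make_sphere(spec: SphereSpec | float, margin: int = 2, angle: float = 0.0) -> BinaryVolume:
    """Voxelize a solid sphere.

    A voxel is foreground iff the distance from its center to the sphere
    center (grid center plus the spec's sub-voxel offset) is <= radius.  The
    grid side is ``ceil(2 r) + 2 margin + 1`` so the object never touches the
    border for margin >= 1.
    """
    if not isinstance(spec, SphereSpec):
        spec = SphereSpec(radius=float(spec), angle=angle)
    r = spec.radius
    side = int(math.ceil(2 * r)) + 2 * margin + 1
    center = np.array([(side - 1) / 2.0] * 3) + np.array(spec.center_offset)
    ax = np.arange(side)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return BinaryVolume(d2 <= r * r)


def make_cube(side: int, margin: int = 2) -> BinaryVolume:
    """Axis-aligned solid cube of the given side, centered in a padded grid."""
    if side < 1:
        raise ValueError("cube side must be >= 1")
    n = side + 2 * margin
    grid = np.zeros((n, n, n), dtype=bool)
    grid[margin:margin + side, margin:margin + side, margin:margin + side] = True
    return BinaryVolume(grid)


def make_bumpy_sphere(
    radius: float,
    bump_amplitude: float = 0.0,
    bump_frequency: int = 6,
    margin: int = 2,
) -> BinaryVolume:
    """Sphere with a sinusoidal angular perturbation of its radius.

    Foreground iff ``d <= radius + A sin(f*theta) sin(f*phi)`` where theta is
    the polar and phi the azimuthal angle of the voxel center.  A stand-in for
    a gyrified surface: amplitude 0 reduces exactly to ``make_sphere`` with
    zero offset.
    """
    if radius < 1:
        raise ValueError("sphere radius must be >= 1 voxel")
    if bump_amplitude < 0:
        raise ValueError("bump amplitude must be >= 0")
    if bump_frequency < 1:
        raise ValueError("bump frequency must be >= 1")
    rmax = radius + bump_amplitude
    side = int(math.ceil(2 * rmax)) + 2 * margin + 1
    c = (side - 1) / 2.0
    ax = np.arange(side) - c
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    d = np.sqrt(x * x + y * y + z * z)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.divide(z, d, out=np.zeros_like(d), where=d > 0))
    phi = np.arctan2(y, x)
    rloc = radius + bump_amplitude * np.sin(bump_frequency * theta) * np.sin(bump_frequency * phi)
    return BinaryVolume(d <= rloc)
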