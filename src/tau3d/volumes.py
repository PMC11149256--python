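"""Binary 3D voxel volumes: I/O, slicing, and morphological smoothing.

A volume is a boolean occupancy grid indexed ``(x, y, z)``.  The voxel at
index ``(i, j, k)`` occupies the unit cube ``[i, i+1) x [j, j+1) x [k, k+1)``,
so the crack-boundary vertices produced by contour tracing land on integer
lattice points.  The tortuosity measure is unit-free; grids are assumed
isotropic and any NIfTI affine/orientation information is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

Axis = Literal["X", "Y", "Z"]

AXES: tuple[Axis, Axis, Axis] = ("X", "Y", "Z")
_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


@dataclass
class BinaryVolume:
    """A 3D boolean occupancy grid.

    Parameters
    ----------
    grid
        3D boolean array indexed ``(x, y, z)``.  Any array convertible to
        bool is accepted and binarized strictly.
    spacing
        Isotropic voxel edge length.  Dimensionless; the measure itself is
        scale-free, so this is carried only as metadata.
    """

    grid: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError(f"volume grid must be 3-dimensional, got {grid.ndim}D")
        if any(s < 1 for s in grid.shape):
            raise ValueError(f"all extents must be >= 1, got shape {grid.shape}")
        self.grid = grid.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    def touches_border(self) -> bool:
        g = self.grid
        return bool(
            g[0].any() or g[-1].any()
            or g[:, 0].any() or g[:, -1].any()
            or g[:, :, 0].any() or g[:, :, -1].any()
        )

    def padded(self, width: int = 1) -> "BinaryVolume":
        """Return a copy with ``width`` empty voxels added on every face."""
        return BinaryVolume(np.pad(self.grid, width), spacing=self.spacing)


@dataclass
class SlicePlane:
    """One 2D cross-section of a volume perpendicular to ``axis``.

    For axis X the mask is indexed ``(y, z)``; for Y, ``(x, z)``; for Z,
    ``(x, y)`` — i.e. the two remaining coordinates in their original order.
    """

    axis: Axis
    index: int
    mask: np.ndarray = field(repr=False)

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


def load_volume(path: str | Path, threshold: float = 0.5) -> BinaryVolume:
    """Load a NIfTI (.nii/.nii.gz) or .npy file and binarize at ``threshold``.

    Foreground is ``intensity > threshold``.  An empty foreground is allowed
    at load time; tortuosity operations reject it later.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D array in {path}, got {data.ndim}D")
    return BinaryVolume(data > threshold)


def save_volume(vol: BinaryVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (identity affine) or .npy, by extension."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, vol.grid.astype(np.uint8))
    else:
        import nibabel as nib

        img = nib.Nifti1Image(vol.grid.astype(np.uint8), affine=np.eye(4))
        nib.save(img, str(path))


def extract_slices(vol: BinaryVolume, axis: Axis) -> list[SlicePlane]:
    """All cross-sections of ``vol`` along ``axis``, in increasing index order.

    Empty slices are included (callers decide whether they count); the masks
    are views where possible, so restacking them reproduces the grid exactly.
    """
    ax = _AXIS_INDEX[axis]
    moved = np.moveaxis(vol.grid, ax, 0)
    return [SlicePlane(axis=axis, index=i, mask=moved[i]) for i in range(moved.shape[0])]


def iter_nonempty_slices(vol: BinaryVolume, axis: Axis) -> Iterator[SlicePlane]:
    for plane in extract_slices(vol, axis):
        if not plane.is_empty:
            yield plane


def ball_element(radius: int) -> np.ndarray:
    """Discrete ball: all offsets within Euclidean distance ``radius``."""
    if radius < 1:
        raise ValueError("structuring-element radius must be >= 1")
    r = int(radius)
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= radius * radius


def morphological_closing(vol: BinaryVolume, radius: int) -> BinaryVolume:
    """Dilation then erosion by a discrete ball of the given radius.

    The grid is zero-padded internally by ``radius`` so the dilated object can
    never be truncated at the array border, then cropped back to the input
    shape.  Closing is extensive (output foreground contains the input) and
    idempotent.
    """
    from scipy import ndimage

    ball = ball_element(radius)
    padded = np.pad(vol.grid, radius)
    closed = ndimage.binary_erosion(ndimage.binary_dilation(padded, structure=ball), structure=ball)
    r = radius
    return BinaryVolume(closed[r:-r, r:-r, r:-r], spacing=vol.spacing)
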