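"""Voxel-grid geometry helpers shared across the package.

Axis convention (patient coordinate system):
    axis 0 (x): toward patient left
    axis 1 (y): toward posterior
    axis 2 (z): toward superior (slice axis)
Arrays are indexed ``[ix, iy, iz]``; physical coordinates are in mm with the
origin at the grid centre, ``phys = (idx - (n - 1) / 2) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: shape in voxels, anisotropic spacing in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("Grid is three-dimensional")
        if any(n < 2 for n in self.shape):
            raise ValueError(f"grid shape too small: {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive: {self.spacing}")

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def shape_arr(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=int)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_arr))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def half_extent(self) -> np.ndarray:
        """Half physical extent per axis (mm)."""
        return (self.shape_arr - 1) * self.spacing_arr / 2.0

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing[axis]

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable physical coordinate arrays (x, y, z) in mm."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def phys_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for physical points (..., 3)."""
        pts = np.asarray(pts_mm, dtype=float)
        return pts / self.spacing_arr + (self.shape_arr - 1) / 2.0

    def index_to_phys(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return (idx - (self.shape_arr - 1) / 2.0) * self.spacing_arr


def mask_volume_cc(mask: np.ndarray, grid: Grid) -> float:
    return float(np.count_nonzero(mask)) * grid.voxel_volume_cc


def mask_com_mm(mask: np.ndarray, grid: Grid) -> np.ndarray:
    """Centre of mass of a binary mask in physical mm."""
    if not mask.any():
        raise ValueError("empty mask has no centre of mass")
    com_idx = np.asarray(ndimage.center_of_mass(mask.astype(np.float64)))
    return grid.index_to_phys(com_idx)


def sample_at_physical(
    values: np.ndarray, grid: Grid, pts_mm: np.ndarray, cval: float = 0.0, order: int = 1
) -> np.ndarray:
    """Interpolate a scalar volume at physical points (..., 3)."""
    idx = grid.phys_to_index(pts_mm)
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        values.astype(np.float64, copy=False), coords, order=order, mode="constant", cval=cval
    )
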