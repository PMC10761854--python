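"""Voxel-grid geometry shared by all volumetric stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Shape and voxel-to-world affine of a volume grid.

    The affine maps voxel indices ``(i, j, k)`` to millimetre coordinates
    (MNI-style world space), following the NIfTI convention.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_size_mm: float) -> "GridGeometry":
        """Centered isotropic grid: world origin at the grid's midpoint."""
        shape = tuple(int(s) for s in shape)
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
        # put mm-origin at the geometric center of the voxel-center cloud
        aff[:3, 3] = -voxel_size_mm * (np.array(shape) - 1) / 2.0
        return cls(shape=shape, affine=aff)

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to mm coordinates (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_centers_mm(self) -> np.ndarray:
        """mm coordinates of every voxel center, shape (*grid, 3)."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1)
        return self.voxel_to_mm(idx)

    def contains_mm(self, point_mm) -> bool:
        """True when the point lies inside the voxel-center bounding box."""
        centers = self.voxel_to_mm(np.array([[0, 0, 0], [s - 1 for s in self.shape]]))
        lo, hi = np.minimum(*centers), np.maximum(*centers)
        p = np.asarray(point_mm, dtype=float)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def sphere_voxels(self, center_mm, radius_mm: float) -> np.ndarray:
        """Indices (n, 3) of voxels whose centers lie within radius of center."""
        d = self.voxel_centers_mm() - np.asarray(center_mm, dtype=float)
        inside = np.einsum("...i,...i->...", d, d) <= float(radius_mm) ** 2
        return np.argwhere(inside)
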