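"""Shared containers for volumetric fMRI data on a common grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Bold4D:
    """A 4D BOLD run: (x, y, z, t) voxel data plus geometry and timing.

    ``affine`` maps voxel indices to scanner mm coordinates (NIfTI
    convention); ``mask`` is the brain mask on the same grid.
    """

    data: np.ndarray          # float array, shape (X, Y, Z, T)
    affine: np.ndarray        # 4x4 voxel -> mm
    tr_seconds: float
    mask: np.ndarray          # bool, shape (X, Y, Z)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("Bold4D data must be 4-dimensional")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_ul(self) -> float:
        """Voxel volume in microliters (1 mm^3 == 1 ul)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def volume(self, t: int) -> np.ndarray:
        return self.data[..., t]


def voxel_to_mm(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (..., 3) to mm coordinates through the affine."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def mm_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map mm coordinates (..., 3) to (fractional) voxel indices."""
    xyz = np.asarray(xyz, dtype=float)
    inv = np.linalg.inv(affine[:3, :3])
    return (xyz - affine[:3, 3]) @ inv.T


def centered_affine(grid_shape, voxel_size_mm: float) -> np.ndarray:
    """Isotropic affine placing the grid center at mm origin."""
    shape = np.asarray(grid_shape, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * voxel_size_mm
    aff[:3, 3] = -voxel_size_mm * (shape - 1) / 2.0
    return aff
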