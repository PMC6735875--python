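"""3D image and label volumes with voxel-to-world affines.

Volumes follow the NIfTI convention: voxel indices are 0-based, the affine
maps an integer index to the world-mm coordinate of that voxel's centre.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


class VolumeError(ValueError):
    """Raised for inconsistent or invalid volume data."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise VolumeError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeError("affine is singular (not invertible)")
    return affine


@dataclass
class ImageVolume:
    """Scalar 3D volume (signal intensity, arbitrary units)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise VolumeError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.affine = _check_affine(self.affine)
        if np.any(self.spacing_mm <= 0):
            raise VolumeError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to world-mm coordinates of voxel centres."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine)


@dataclass
class LabelVolume:
    """Binary 3D mask sharing the grid and affine of a parent image."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeError(f"label data must be 3D, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise VolumeError(f"label values must be in {{0, 1}}, found {uniq}")
        self.data = arr.astype(np.uint8)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-9)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0.5, img.affine)
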