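"""Rigid transforms and least-squares landmark registration.

The image and mapping coordinate frames are related by a rigid motion
(rotation + translation). Landmark registration recovers it from ordered
point correspondences by the Kabsch / orthogonal-Procrustes solution:
centre both clouds, take the SVD of the cross-covariance, and correct any
reflection by flipping the sign of the smallest singular vector.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class TransformError(ValueError):
    """Raised for invalid transforms or degenerate landmark sets."""


@dataclass
class RigidTransform:
    """Proper rigid motion p -> R p + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise TransformError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise TransformError("rotation is not orthonormal (R^T R != I)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise TransformError("rotation determinant is not +1 (improper rotation)")
        self.rotation = R
        self.translation = t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler_deg(cls, rx: float = 0.0, ry: float = 0.0, rz: float = 0.0,
                       translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from extrinsic x-y-z rotations in degrees plus translation."""
        ax, ay, az = np.deg2rad([rx, ry, rz])
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(Rz @ Ry @ Rx, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees.

        Uses atan2 of (|sin|, cos) from the skew part and trace, which stays
        accurate for very small angles where arccos loses precision.
        """
        R = self.rotation
        axis = 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        s = np.linalg.norm(axis)
        c = (np.trace(R) - 1.0) / 2.0
        return float(np.degrees(np.arctan2(s, c)))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


@dataclass
class LandmarkSet:
    """Ordered corresponding point pairs (mm) between two frames."""

    source: np.ndarray
    destination: np.ndarray

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.source, dtype=float))
        dst = np.atleast_2d(np.asarray(self.destination, dtype=float))
        if src.shape != dst.shape or src.shape[1] != 3:
            raise TransformError("source/destination must be matching (N, 3) arrays")
        if len(src) < 3:
            raise TransformError(f"need >= 3 landmark pairs, got {len(src)}")
        if _collinear(src):
            raise TransformError("source landmarks are collinear (rotation under-determined)")
        self.source = src
        self.destination = dst

    def __len__(self) -> int:
        return len(self.source)


def fit_rigid_landmarks(landmarks: LandmarkSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of destination = R source + t (Kabsch).

    Returns the transform and the RMS residual (mm) over the landmark pairs.
    """
    src, dst = landmarks.source, landmarks.destination
    src_c = src.mean(axis=0)
    dst_c = dst.mean(axis=0)
    H = (src - src_c).T @ (dst - dst_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dst_c - R @ src_c
    T = RigidTransform(R, t)
    residuals = T.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return T, rms


def apply_transform(points: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply a rigid transform to an (N, 3) point array (or a single point)."""
    return transform.apply(points)
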