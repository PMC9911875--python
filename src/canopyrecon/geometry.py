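"""Rigid 3-D transforms and small rotation helpers.

Everything downstream (coarse translation matrices, ICP refinements, cloud
leveling) is expressed as a 4x4 homogeneous :class:`RigidTransform`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "rotation_about_axis", "rotation_aligning"]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion as a 4x4 homogeneous matrix.

    The upper-left 3x3 block must be a rotation (orthonormal, det = +1);
    pure translations — e.g. the coarse inter-frame matrix built from the
    estimated platform displacement — are the special case R = I.
    """

    M: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {M.shape}")
        if not np.allclose(M[3], [0.0, 0.0, 0.0, 1.0], atol=_ORTHO_TOL):
            raise ValueError("bottom row must be (0, 0, 0, 1)")
        R = M[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-5):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block has det < 0 (reflection)")
        object.__setattr__(self, "M", M)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        M = np.eye(4)
        M[:3, 3] = np.asarray(t, dtype=float)
        return cls(M)

    @classmethod
    def from_rotation_translation(cls, R, t) -> "RigidTransform":
        M = np.eye(4)
        M[:3, :3] = np.asarray(R, dtype=float)
        M[:3, 3] = np.asarray(t, dtype=float)
        return cls(M)

    # -- accessors ---------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.M[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.M[:3, 3]

    # -- algebra -----------------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.M @ other.M)

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        t = self.translation
        M = np.eye(4)
        M[:3, :3] = R.T
        M[:3, 3] = -R.T @ t
        return RigidTransform(M)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a (not necessarily unit) axis."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n < 1e-15:
        return np.eye(3)
    a = a / n
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def rotation_aligning(src, dst) -> np.ndarray:
    """Smallest rotation taking unit-ish vector ``src`` onto ``dst``."""
    a = np.asarray(src, dtype=float)
    b = np.asarray(dst, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        return rotation_about_axis(axis, np.pi)
    angle = np.arctan2(np.linalg.norm(v), c)
    return rotation_about_axis(v, angle)
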