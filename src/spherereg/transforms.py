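"""Rigid and similarity transforms between labelled coordinate frames.

A :class:`RigidTransform` maps points from ``frame_from`` to ``frame_to`` as

    y = scale * R @ x + t

with ``R`` a proper rotation. ``scale`` is 1.0 for strictly Euclidean maps and
only differs from 1 when relating a metric frame (e.g. an optical scan in mm)
to a structure-from-motion world whose scale is arbitrary.

Frame labels are plain strings ("S" scan-local, "W" camera world, "B" robot
base, "EE" end-effector, "C" camera). Composition checks that the labels chain,
which catches the single most common integration bug in pose plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import FrameMismatchError, SphereregError

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0
    frame_from: str = "A"
    frame_to: str = "B"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise SphereregError("non-finite entries in transform")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise SphereregError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise SphereregError("rotation has negative determinant (reflection)")
        if self.scale <= 0:
            raise SphereregError(f"scale must be positive, got {self.scale}")
        # re-orthonormalise tiny drift so long composition chains stay valid
        if np.abs(R.T @ R - np.eye(3)).max() > _ORTHO_TOL:
            U, _, Vt = np.linalg.svd(R)
            object.__setattr__(self, "rotation", U @ Vt)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls, frame: str = "A") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 1.0, frame, frame)

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, frame_from: str = "A", frame_to: str = "B"
    ) -> "RigidTransform":
        """Build from a homogeneous 4x4 ``[[s*R, t], [0, 1]]`` matrix."""
        M = np.asarray(matrix, dtype=float).reshape(4, 4)
        A = M[:3, :3]
        s = float(np.cbrt(np.linalg.det(A)))
        if s <= 0:
            raise SphereregError("matrix upper-left block has non-positive determinant")
        return cls(A / s, M[:3, 3], s, frame_from, frame_to)

    @classmethod
    def from_quaternion(
        cls,
        qwxyz: np.ndarray,
        translation: np.ndarray,
        frame_from: str = "A",
        frame_to: str = "B",
        scale: float = 1.0,
    ) -> "RigidTransform":
        """Quaternion in (w, x, y, z) order, the COLMAP text convention."""
        q = np.asarray(qwxyz, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-9:
            raise SphereregError(f"quaternion norm {n!r} differs from 1 by more than 1e-9")
        R = Rotation.from_quat(np.r_[q[1:], q[0]]).as_matrix()  # scipy wants xyzw
        return cls(R, translation, scale, frame_from, frame_to)

    # -- core algebra ------------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.scale * self.rotation
        M[:3, 3] = self.translation
        return M

    def quaternion_wxyz(self) -> np.ndarray:
        q = Rotation.from_matrix(self.rotation).as_quat()  # xyzw
        q = np.r_[q[3], q[:3]]
        return q if q[0] >= 0 else -q

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from ``frame_from`` into ``frame_to``."""
        p = np.asarray(points, dtype=float)
        return self.scale * p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self`` (matrix product)."""
        if other.frame_to != self.frame_from:
            raise FrameMismatchError(
                f"cannot compose: inner transform maps to frame "
                f"{other.frame_to!r} but outer expects {self.frame_from!r}"
            )
        return RigidTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
            self.scale * other.scale,
            other.frame_from,
            self.frame_to,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            Rinv,
            -Rinv @ self.translation / self.scale,
            1.0 / self.scale,
            self.frame_to,
            self.frame_from,
        )

    # -- diagnostics -------------------------------------------------------

    def rotation_angle_to(self, other: "RigidTransform") -> float:
        """Geodesic angle (rad) between the two rotations."""
        dR = self.rotation.T @ other.rotation
        c = np.clip((np.trace(dR) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.arccos(c))

    def translation_distance_to(self, other: "RigidTransform") -> float:
        return float(np.linalg.norm(self.translation - other.translation))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Matrix-product composition ``a @ b`` with frame-label checking."""
    return a.compose(b)


def random_rigid_transform(
    rng: np.random.Generator,
    frame_from: str = "A",
    frame_to: str = "B",
    translation_scale: float = 100.0,
    scale: float = 1.0,
) -> RigidTransform:
    """Uniformly random rotation, Gaussian translation — test/simulation helper."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=translation_scale, size=3)
    return RigidTransform(R, t, scale, frame_from, frame_to)
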