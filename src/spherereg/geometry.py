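"""Projective geometry of spheres and their image ellipses.

A sphere with centre c and radius r is the quadric

    Q = [[ I, -c ], [ -c^T, c^T c - r^2 ]],        x~^T Q x~ = 0 on the surface,

and its dual (the adjugate, up to scale) has the rank-friendly closed form

    Q* ∝ c~ c~^T - r^2 diag(1, 1, 1, 0),            c~ = (c, 1).

Under a pinhole camera with 3x4 projection matrix P the sphere's silhouette is
the conic E with  E^-1 ∝ P Q^-1 P^T; any image point x on the silhouette
satisfies the bilinear identity x~^T E x~ = 0, which is the residual the
registration objective minimises.

Conics are scale-equivalence classes; throughout we normalise to unit
Frobenius norm with positive trace of the upper-left 2x2 block, so that
residual magnitudes are comparable across markers and images and the interior
of an ellipse evaluates negative.

Pixel convention: 0-based, x right / y down, origin at the centre of the
top-left pixel (COLMAP-adjacent). Distances are millimetres, image units are
pixels. Camera poses map world W to camera C; no lens distortion is modelled
(undistortion is assumed upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateConicError,
    DegenerateSilhouetteError,
    SphereregError,
)
from .transforms import RigidTransform


@dataclass(frozen=True)
class Camera:
    """Pinhole camera: intrinsics in pixels plus a world-to-camera pose."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    pose: RigidTransform  # maps frame W -> C, scale 1
    camera_id: str = ""

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise SphereregError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise SphereregError("principal point must lie inside the image")
        if abs(self.pose.scale - 1.0) > 1e-12:
            raise SphereregError("camera poses must be strictly rigid (scale 1)")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def P(self) -> np.ndarray:
        """3x4 projection matrix K [R | t]."""
        Rt = np.hstack([self.pose.rotation, self.pose.translation[:, None]])
        return self.K @ Rt

    @property
    def center_world(self) -> np.ndarray:
        """Camera centre expressed in the world frame."""
        return -self.pose.rotation.T @ self.pose.translation

    def project_points(self, points_world: np.ndarray) -> np.ndarray:
        """Project (..., 3) world points to (..., 2) pixel coordinates."""
        pc = self.pose.apply(points_world)
        z = pc[..., 2]
        if np.any(z <= 0):
            raise SphereregError("point at or behind the camera cannot be projected")
        return np.stack(
            [self.fx * pc[..., 0] / z + self.cx, self.fy * pc[..., 1] / z + self.cy],
            axis=-1,
        )

    def back_project_rays(self, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (origin (3,), unit directions (...,3)) of viewing rays in W."""
        px = np.asarray(pixels, dtype=float)
        d_cam = np.stack(
            [
                (px[..., 0] - self.cx) / self.fx,
                (px[..., 1] - self.cy) / self.fy,
                np.ones_like(px[..., 0]),
            ],
            axis=-1,
        )
        d_world = d_cam @ self.pose.rotation  # R^T d
        d_world = d_world / np.linalg.norm(d_world, axis=-1, keepdims=True)
        return self.center_world, d_world


@dataclass(frozen=True)
class SphereMarker:
    """Spherical fiducial: centre (mm) tagged with its frame, known radius (mm)."""

    center: np.ndarray
    radius: float
    frame: str = "S"
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "radius", float(self.radius))
        if self.radius <= 0:
            raise SphereregError(f"sphere radius must be positive, got {self.radius}")

    def transformed(self, T: RigidTransform) -> "SphereMarker":
        """Map the marker through T; a similarity scales the radius too."""
        if T.frame_from != self.frame:
            raise SphereregError(
                f"transform maps from {T.frame_from!r} but marker lives in {self.frame!r}"
            )
        return SphereMarker(T.apply(self.center), T.scale * self.radius, T.frame_to, self.label)


def sphere_quadric(marker: SphereMarker) -> np.ndarray:
    """4x4 symmetric quadric Q with x~^T Q x~ = 0 iff ||x - c|| = r."""
    c = marker.center
    Q = np.eye(4)
    Q[:3, 3] = -c
    Q[3, :3] = -c
    Q[3, 3] = c @ c - marker.radius**2
    return Q


def sphere_dual_quadric(marker: SphereMarker) -> np.ndarray:
    """Dual quadric Q* = c~ c~^T - r^2 diag(1,1,1,0)  (adjugate of Q up to scale)."""
    ch = np.r_[marker.center, 1.0]
    Qd = np.outer(ch, ch)
    Qd[:3, :3] -= marker.radius**2 * np.eye(3)
    return Qd


class Conic:
    """A 3x3 symmetric image conic, stored in normalised form.

    Normalisation: symmetric, unit Frobenius norm, trace of the upper-left 2x2
    block non-negative. Points on the curve satisfy x~^T E x~ = 0; for an
    ellipse the interior evaluates negative under this sign convention.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        M = np.asarray(matrix, dtype=float).reshape(3, 3)
        M = 0.5 * (M + M.T)
        n = np.linalg.norm(M)
        if n == 0 or not np.all(np.isfinite(M)):
            raise DegenerateConicError("zero or non-finite conic matrix")
        M = M / n
        if np.trace(M[:2, :2]) < 0:
            M = -M
        self.matrix = M
        self.matrix.flags.writeable = False

    # -- predicates --------------------------------------------------------

    @property
    def is_ellipse(self) -> bool:
        A = self.matrix[:2, :2]
        if np.linalg.det(A) <= 0:
            return False
        # real (non-empty, non-point) ellipse: centre value must be negative
        try:
            ctr = np.linalg.solve(A, -self.matrix[:2, 2])
        except np.linalg.LinAlgError:
            return False
        ch = np.r_[ctr, 1.0]
        return bool(ch @ self.matrix @ ch < 0)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Bilinear residual x~^T E x~ at pixel points (..., 2)."""
        p = np.asarray(points, dtype=float)
        x, y = p[..., 0], p[..., 1]
        M = self.matrix
        return (
            M[0, 0] * x * x
            + 2 * M[0, 1] * x * y
            + M[1, 1] * y * y
            + 2 * M[0, 2] * x
            + 2 * M[1, 2] * y
            + M[2, 2]
        )

    # -- parameter conversions ---------------------------------------------

    @classmethod
    def from_params(
        cls, center: np.ndarray, semi_axes: np.ndarray, angle: float
    ) -> "Conic":
        """Ellipse from (centre px, semi-axes a>=b px, major-axis angle rad)."""
        cx, cy = np.asarray(center, dtype=float)
        a, b = np.asarray(semi_axes, dtype=float)
        if a <= 0 or b <= 0:
            raise DegenerateConicError("semi-axes must be positive")
        ca, sa = np.cos(angle), np.sin(angle)
        Rt = np.array([[ca, sa], [-sa, ca]])  # rotate world into axis-aligned frame
        A_aligned = np.diag([1.0 / a**2, 1.0 / b**2])
        A = Rt.T @ A_aligned @ Rt
        c = np.array([cx, cy])
        M = np.zeros((3, 3))
        M[:2, :2] = A
        M[:2, 2] = -A @ c
        M[2, :2] = -A @ c
        M[2, 2] = c @ A @ c - 1.0
        return cls(M)

    def params(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Decompose into (centre px, semi-axes a>=b px, angle in (-pi/2, pi/2])."""
        M = self.matrix
        A = M[:2, :2]
        if np.linalg.det(A) <= 0:
            raise DegenerateConicError("conic is not an ellipse (non-PD quadratic part)")
        center = np.linalg.solve(A, -M[:2, 2])
        ch = np.r_[center, 1.0]
        mu = -float(ch @ M @ ch)  # positive for a real ellipse
        if mu <= 0:
            raise DegenerateConicError("conic is an empty/point ellipse")
        lam, vec = np.linalg.eigh(A)  # ascending; lam[0] -> major axis
        axes = np.sqrt(mu / lam)  # a >= b
        v = vec[:, 0]
        angle = float(np.arctan2(v[1], v[0]))
        if angle <= -np.pi / 2:
            angle += np.pi
        elif angle > np.pi / 2:
            angle -= np.pi
        if lam[1] - lam[0] <= 1e-14 * lam[1]:  # relative test only: the
            angle = 0.0  # eigenvalues are tiny, an absolute atol would misfire
        return center, axes, angle

    def sample_outline(self, n: int) -> np.ndarray:
        """n points uniformly spaced in parametric angle, each on the conic."""
        if n < 4:
            raise SphereregError(f"need at least 4 outline samples, got {n}")
        center, (a, b), phi = self.params()
        theta = 2 * np.pi * np.arange(n) / n
        u = np.array([np.cos(phi), np.sin(phi)])
        v = np.array([-np.sin(phi), np.cos(phi)])
        return center + np.outer(a * np.cos(theta), u) + np.outer(b * np.sin(theta), v)

    def __repr__(self) -> str:  # pragma: no cover
        try:
            c, ax, ang = self.params()
            return f"Conic(center={c.round(2)}, axes={ax.round(2)}, angle={ang:.3f})"
        except DegenerateConicError:
            return f"Conic(non-ellipse, matrix={self.matrix.round(4)})"


def conic_to_params(conic: Conic) -> tuple[np.ndarray, np.ndarray, float]:
    """Functional alias for :meth:`Conic.params`."""
    return conic.params()


def sample_outline(conic: Conic, n: int) -> np.ndarray:
    """Functional alias for :meth:`Conic.sample_outline`."""
    return conic.sample_outline(n)


def project_sphere(marker: SphereMarker, cam: Camera) -> Conic:
    """Silhouette conic of a sphere under a pinhole camera (dual-quadric projection).

    The marker must be expressed in the camera's world frame. Raises
    :class:`DegenerateSilhouetteError` if the sphere centre is at or behind the
    camera's principal plane, or the sphere encloses the camera centre.
    """
    if marker.frame != cam.pose.frame_from:
        raise SphereregError(
            f"marker frame {marker.frame!r} does not match camera world frame "
            f"{cam.pose.frame_from!r}"
        )
    c_cam = cam.pose.apply(marker.center)
    d = np.linalg.norm(c_cam)
    if d <= marker.radius:
        raise DegenerateSilhouetteError(
            "degenerate silhouette: sphere encloses the camera centre"
        )
    if c_cam[2] <= 0:
        raise DegenerateSilhouetteError(
            "degenerate silhouette: sphere centre behind the camera"
        )
    # E^-1 = P Q^-1 P^T reduced in closed form: with B = K R one has
    # B B^T = K K^T exactly, and a Sherman-Morrison step on the rank-1 dual
    # quadric yields  E ∝ K^-T (c c^T - (||c||^2 - r^2) I) K^-1  with c the
    # sphere centre in the camera frame. This avoids inverting the badly
    # conditioned dual conic (its rank-1 part dominates by ~|c|^2/r^2).
    Kinv = np.linalg.inv(cam.K)
    inner = np.outer(c_cam, c_cam) - (d**2 - marker.radius**2) * np.eye(3)
    return Conic(Kinv.T @ inner @ Kinv)
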