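"""Shared fixtures: small fully-specified scenes with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spherereg import (
    Camera,
    ObservationSet,
    RigidTransform,
    SceneConfig,
    SphereMarker,
    generate_scene,
    project_sphere,
    sample_outline,
)


def look_at(eye, target, frame_from="W"):
    """World-to-camera pose looking from eye toward target."""
    eye = np.asarray(eye, float)
    target = np.asarray(target, float)
    z = target - eye
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    if abs(z @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    return RigidTransform(R, -R @ eye, 1.0, frame_from, "C")


def make_camera(eye=(600.0, 0.0, 800.0), target=(0.0, 0.0, 0.0), f=7000.0,
                width=9504, height=6336):
    return Camera(f, f, (width - 1) / 2, (height - 1) / 2, width, height,
                  look_at(eye, target))


def random_visible_pair(rng, f=2000.0, width=4000, height=3000):
    """Random (sphere, camera) pair with the sphere fully visible."""
    cam = Camera(f, f, (width - 1) / 2, (height - 1) / 2, width, height,
                 look_at(rng.normal(scale=300, size=3) + [0, 0, 1500], [0, 0, 0]))
    # sphere near the optical axis, well in front
    for _ in range(100):
        c = rng.uniform(-250, 250, 3)
        m = SphereMarker(c, rng.uniform(5, 40), "W")
        cc = cam.pose.apply(c)
        if cc[2] > 3 * m.radius:
            px = cam.project_points(c)
            if 200 < px[0] < width - 200 and 200 < px[1] < height - 200:
                return m, cam
    raise RuntimeError("could not place a visible sphere")


def silhouette_pixels(m: SphereMarker, cam: Camera, n=10_000):
    """Brute-force silhouette via the tangent cone: the independent oracle
    for the analytic conic projection."""
    c_cam = cam.pose.apply(m.center)
    d = np.linalg.norm(c_cam)
    axis = c_cam / d
    half = np.arcsin(m.radius / d)
    # orthonormal basis around the axis
    a = np.array([1.0, 0.0, 0.0])
    if abs(axis @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    th = 2 * np.pi * np.arange(n) / n
    dirs = (
        np.cos(half) * axis[None, :]
        + np.sin(half) * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)
    )
    return np.stack(
        [
            cam.fx * dirs[:, 0] / dirs[:, 2] + cam.cx,
            cam.fy * dirs[:, 1] / dirs[:, 2] + cam.cy,
        ],
        axis=1,
    )


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free default scene (M=10, N=16, L=20, full-res intrinsics)."""
    return generate_scene(SceneConfig(seed=20240917, mesh_subdivisions=2))


@pytest.fixture(scope="session")
def noisy_scene():
    return generate_scene(
        SceneConfig(seed=20240918, outline_noise_px=0.5, mesh_noise_mm=0.05,
                    mesh_subdivisions=3)
    )
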