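"""Synthetic scenes with exact ground truth for every pipeline stage.

The generator emulates the physical acquisition setup this package targets: a
specimen on a table surrounded by M spherical fiducials of known radius, an
optical scan of the scene (a noisy triangulated mesh in a scan-local frame S),
and N calibrated high-resolution viewpoints looking at the scene from an arc
above it (as a camera on a robot arm would). Ground truth — the scan-to-world
transform, every silhouette conic, every outline point — is available by
construction, so registration accuracy can be measured exactly.

Two intrinsics presets:

* ``fullres`` — 9504x6336 px sensor, f = 7000 px, scene at ~1 m: a 30 mm
  marker then spans roughly 200 px, matching a full-frame mirrorless camera
  with a standard zoom at portrait distance.
* ``desk`` — 1920x1080 px, f = 1500 px: keeps rendered-image tests fast.

All randomness flows from a single integer seed; equal seeds give identical
scenes, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import SphereregError
from .geometry import Camera, Conic, SphereMarker, project_sphere, sample_outline
from .markers import SurfaceMesh
from .observations import EllipseDetection, ObservationSet
from .transforms import RigidTransform

PRESETS = {
    "fullres": dict(width=9504, height=6336, f=7000.0),
    "desk": dict(width=1920, height=1080, f=1500.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Full specification of a synthetic scene; the defaults mirror the
    evaluation protocol the package is designed around: M = 10 markers of
    30 mm diameter, N = 16 viewpoints at ~1 m."""

    M: int = 10
    marker_radius: float = 15.0
    marker_layout: str = "ring"  # ring | board
    layout_extent: float = 150.0  # ring radius / half board side, mm
    N: int = 16
    camera_distance: float = 1000.0
    preset: str = "fullres"
    n_outline_points: int = 20
    outline_noise_px: float = 0.0
    mesh_noise_mm: float = 0.0
    mesh_coverage: str = "full"  # full | hemisphere
    mesh_subdivisions: int = 4
    n_control_markers: int = 3
    true_transform: RigidTransform | None = None
    true_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1 or self.n_outline_points < 4:
            raise SphereregError("counts must be positive (and L >= 4)")
        if self.outline_noise_px < 0 or self.mesh_noise_mm < 0:
            raise SphereregError("noise levels must be non-negative")
        if self.preset not in PRESETS:
            raise SphereregError(f"unknown preset {self.preset!r}")
        if self.marker_layout not in ("ring", "board"):
            raise SphereregError(f"unknown layout {self.marker_layout!r}")
        if self.mesh_coverage not in ("full", "hemisphere"):
            raise SphereregError(f"unknown coverage {self.mesh_coverage!r}")
        if self.true_scale <= 0:
            raise SphereregError("true_scale must be positive")


@dataclass(frozen=True)
class SyntheticScene:
    """Everything :func:`generate_scene` produces."""

    config: SceneConfig
    markers: list[SphereMarker]  # registration markers, frame S
    control_markers: list[SphereMarker]  # held-out markers, frame S
    cameras: list[Camera]
    exact_observations: ObservationSet
    noisy_observations: ObservationSet
    exact_control_observations: ObservationSet
    mesh: SurfaceMesh
    true_transform: RigidTransform  # S -> W, carries true_scale

    def detections(self, noisy: bool = True) -> list[list[EllipseDetection]]:
        """Per-image detection lists (exact conics; outline points exact or
        noisy), ready for :func:`spherereg.register.register_scene`."""
        obs = self.noisy_observations if noisy else self.exact_observations
        out: list[list[EllipseDetection]] = [[] for _ in self.cameras]
        markers_W = [m.transformed(self.true_transform) for m in self.markers]
        for (i, j), pts in sorted(obs.entries.items()):
            conic = project_sphere(markers_W[j], self.cameras[i])
            out[i].append(
                EllipseDetection(
                    conic=conic,
                    outline_points=conic.sample_outline(self.config.n_outline_points),
                    support_pixel_count=len(pts),
                    image_id=self.cameras[i].camera_id,
                    edge_points=pts,
                )
            )
        return out


def _look_at(eye: np.ndarray, target: np.ndarray) -> RigidTransform:
    """World-to-camera pose looking from eye to target, z forward, y down-ish."""
    z = target - eye
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 0.0, 1.0])
    if abs(z @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    return RigidTransform(R, -R @ eye, 1.0, "W", "C")


def _marker_centers(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Marker centres in frame S. Jitter breaks rotational symmetry so the
    exhaustive correspondence search has a unique answer."""
    r_min = 2.2 * cfg.marker_radius
    if cfg.marker_layout == "ring":
        base = 2 * np.pi * np.arange(cfg.M) / cfg.M
        ang = base + rng.uniform(-0.3, 0.3, cfg.M) * (2 * np.pi / cfg.M)
        rad = cfg.layout_extent * rng.uniform(0.75, 1.25, cfg.M)
        z = rng.uniform(-25.0, 25.0, cfg.M)
        pts = np.stack([rad * np.cos(ang), rad * np.sin(ang), z], axis=1)
    else:  # board: jittered grid
        side = int(np.ceil(np.sqrt(cfg.M)))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        grid = np.stack([gx.ravel(), gy.ravel()], axis=1)[: cfg.M].astype(float)
        grid = (grid / max(side - 1, 1) - 0.5) * 2 * cfg.layout_extent
        grid += rng.uniform(-0.15, 0.15, grid.shape) * cfg.layout_extent
        pts = np.concatenate([grid, rng.uniform(-10, 10, (cfg.M, 1))], axis=1)
    # enforce pairwise separation
    for _ in range(100):
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > r_min:
            break
        pts[i] += (pts[i] - pts[j]) / d[i, j] * (r_min - d[i, j] + 1.0)
    return pts


def _control_centers(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Control markers sit near the scene centre (on/inside the specimen)."""
    n = cfg.n_control_markers
    ang = 2 * np.pi * np.arange(n) / max(n, 1) + rng.uniform(0, 2 * np.pi)
    rad = rng.uniform(0.25, 0.45, n) * cfg.layout_extent
    z = rng.uniform(30.0, 60.0, n)
    return np.stack([rad * np.cos(ang), rad * np.sin(ang), z], axis=1)


def _sphere_mesh(
    center: np.ndarray,
    radius: float,
    subdivisions: int,
    noise_mm: float,
    coverage: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(ico.vertices).copy()
    f = np.asarray(ico.faces).copy()
    if coverage == "hemisphere":
        keep = v[:, 2] > 0  # the scanner sees the upper side only
        idx = -np.ones(len(v), dtype=np.int64)
        idx[keep] = np.arange(keep.sum())
        f = f[np.all(keep[f], axis=1)]
        f = idx[f]
        v = v[keep]
    if noise_mm > 0:
        v = v + rng.normal(scale=noise_mm, size=v.shape)
    return v + center, f


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Build a fully specified synthetic scene from a config.

    Raises if any registration marker would be invisible in some camera —
    the default layouts keep the whole marker set inside every view.
    """
    rng = np.random.default_rng(cfg.seed)
    intr = PRESETS[cfg.preset]
    L = cfg.n_outline_points

    centers_S = _marker_centers(cfg, rng)
    markers = [
        SphereMarker(c, cfg.marker_radius, "S", f"m{k}")
        for k, c in enumerate(centers_S)
    ]
    ctrl_S = _control_centers(cfg, rng)
    control = [
        SphereMarker(c, cfg.marker_radius, "S", f"ctrl{k}")
        for k, c in enumerate(ctrl_S)
    ]

    if cfg.true_transform is None:
        R = Rotation.from_rotvec(rng.uniform(-0.5, 0.5, 3)).as_matrix()
        t = rng.uniform(-80.0, 80.0, 3)
        T_true = RigidTransform(R, t, cfg.true_scale, "S", "W")
    else:
        T_true = replace(
            cfg.true_transform, scale=cfg.true_scale
        ) if cfg.true_transform.scale != cfg.true_scale else cfg.true_transform

    # cameras on two arcs on opposite sides, slightly varying elevation —
    # emulates capture from two robot positions across the table
    scene_center = T_true.apply(centers_S).mean(axis=0)
    cams = []
    for i in range(cfg.N):
        side = 1.0 if i % 2 == 0 else -1.0
        frac = (i // 2) / max(cfg.N // 2 - 1, 1)
        az = side * (np.pi / 2) + (frac - 0.5) * np.pi / 2
        el = np.deg2rad(35.0 + 20.0 * frac)
        eye = scene_center + cfg.camera_distance * np.array(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )
        pose = _look_at(eye, scene_center)
        cams.append(
            Camera(
                intr["f"], intr["f"],
                (intr["width"] - 1) / 2.0, (intr["height"] - 1) / 2.0,
                intr["width"], intr["height"],
                pose, camera_id=f"img{i:03d}",
            )
        )

    def observe(marker_list, noise):
        entries = {}
        for j, m in enumerate(marker_list):
            mw = m.transformed(T_true)
            for i, cam in enumerate(cams):
                conic = project_sphere(mw, cam)
                pts = sample_outline(conic, L)
                inside = (
                    (pts[:, 0] >= 0) & (pts[:, 0] < cam.width)
                    & (pts[:, 1] >= 0) & (pts[:, 1] < cam.height)
                )
                if not inside.all():
                    raise SphereregError(
                        f"marker {m.label} leaves the frame of camera {i}; "
                        "shrink the layout or move the cameras back"
                    )
                if noise > 0:
                    pts = pts + rng.normal(scale=noise, size=pts.shape)
                entries[(i, j)] = pts
        return entries

    exact = ObservationSet(cams, markers, observe(markers, 0.0))
    noisy = ObservationSet(cams, markers, observe(markers, cfg.outline_noise_px))
    exact_ctrl = ObservationSet(cams, control, observe(control, 0.0))

    # mesh: marker spheres + an ellipsoidal specimen blob, in frame S
    verts, faces = [], []
    off = 0
    for m in markers:
        v, f = _sphere_mesh(
            m.center, m.radius, cfg.mesh_subdivisions,
            cfg.mesh_noise_mm, cfg.mesh_coverage, rng,
        )
        verts.append(v)
        faces.append(f + off)
        off += len(v)
    import trimesh

    blob = trimesh.creation.icosphere(subdivisions=cfg.mesh_subdivisions, radius=1.0)
    bv = np.asarray(blob.vertices) * np.array([0.55, 0.3, 0.22]) * cfg.layout_extent
    if cfg.mesh_noise_mm > 0:
        bv = bv + rng.normal(scale=cfg.mesh_noise_mm, size=bv.shape)
    verts.append(bv)
    faces.append(np.asarray(blob.faces) + off)
    mesh = SurfaceMesh(np.concatenate(verts), np.concatenate(faces), "S")

    return SyntheticScene(
        config=cfg,
        markers=markers,
        control_markers=control,
        cameras=cams,
        exact_observations=exact,
        noisy_observations=noisy,
        exact_control_observations=exact_ctrl,
        mesh=mesh,
        true_transform=T_true,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_images(
    scene: SyntheticScene, supersample: int = 4
) -> tuple[list[np.ndarray], list[list[Conic]]]:
    """Anti-aliased renders of bright marker spheres on a textured background.

    Returns per-image float arrays in [0, 1] plus the ground-truth conic
    sidecars. Only sensible with the ``desk`` preset (size gate 4096^2).
    """
    cfg = scene.config
    intr = PRESETS[cfg.preset]
    w, h = intr["width"], intr["height"]
    if w * h > 4096 * 4096:
        raise SphereregError("render size gate: use the desk preset for images")
    rng = np.random.default_rng(cfg.seed + 101)
    images, sidecars = [], []
    markers_W = [m.transformed(scene.true_transform) for m in scene.markers]
    for cam in scene.cameras:
        # low-frequency background texture, dark
        coarse = rng.uniform(0.05, 0.25, size=(h // 40 + 2, w // 40 + 2))
        yy = np.linspace(0, coarse.shape[0] - 1.001, h)
        xx = np.linspace(0, coarse.shape[1] - 1.001, w)
        yi, xi = np.floor(yy).astype(int), np.floor(xx).astype(int)
        fy, fx = (yy - yi)[:, None], (xx - xi)[None, :]
        img = (
            coarse[yi][:, xi] * (1 - fy) * (1 - fx)
            + coarse[yi + 1][:, xi] * fy * (1 - fx)
            + coarse[yi][:, xi + 1] * (1 - fy) * fx
            + coarse[yi + 1][:, xi + 1] * fy * fx
        )
        conics = []
        for mw in markers_W:
            conic = project_sphere(mw, cam)
            conics.append(conic)
            center, (a, b), _ = conic.params()
            x0 = max(int(center[0] - a - 2), 0)
            x1 = min(int(center[0] + a + 3), w)
            y0 = max(int(center[1] - a - 2), 0)
            y1 = min(int(center[1] + a + 3), h)
            if x1 <= x0 or y1 <= y0:
                continue
            ss = supersample
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            sub = (np.arange(ss) + 0.5) / ss - 0.5
            gx = (xs[:, None] + sub[None, :]).ravel()
            gy = (ys[:, None] + sub[None, :]).ravel()
            X, Y = np.meshgrid(gx, gy)
            vals = conic.evaluate(np.stack([X, Y], axis=-1))
            inside = (vals < 0).reshape(len(ys), ss, len(xs), ss)
            coverage = inside.mean(axis=(1, 3))
            patch = img[y0:y1, x0:x1]
            img[y0:y1, x0:x1] = patch + coverage * (1.0 - patch)
        images.append(img)
        sidecars.append(conics)
    return images, sidecars
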