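"""File formats: COLMAP text models, robot pose tables, meshes, reports.

Conventions, stated once and enforced everywhere:

* Stored extrinsics are **world-to-camera**, quaternion in (w, x, y, z) order —
  the COLMAP text-model dialect. Robot pose tables declare their convention in
  a header field and are converted on read.
* Metric data is in millimetres. Structure-from-motion inputs are unit-free
  until similarity registration assigns a scale.
* Pixels are 0-based, x right, y down.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import SphereregError
from .geometry import Camera
from .markers import SurfaceMesh
from .register import RegistrationResult
from .transforms import RigidTransform

_SUPPORTED_MODELS = ("PINHOLE", "SIMPLE_PINHOLE")


def _fmt(v) -> str:
    """repr of a Python float: lossless round-trip, no numpy scalar prefix."""
    return repr(float(v))


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def load_mesh(path: str | Path, frame: str = "S") -> SurfaceMesh:
    """Load a PLY/OBJ/STL surface mesh (units assumed millimetres)."""
    import trimesh

    m = trimesh.load(str(path), force="mesh")
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces), frame)


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    mesh.as_trimesh().export(str(path))


# ---------------------------------------------------------------------------
# COLMAP text model
# ---------------------------------------------------------------------------


def read_colmap_poses(cameras_file: str | Path, images_file: str | Path) -> list[Camera]:
    """Parse COLMAP text ``cameras.txt`` + ``images.txt`` into Camera objects.

    Only PINHOLE and SIMPLE_PINHOLE camera models are supported (the package
    assumes undistorted images); any other model raises with its name. Poses
    are world-to-camera, quaternion (w, x, y, z), per the COLMAP convention.
    """
    intrinsics: dict[int, tuple] = {}
    for ln, line in enumerate(Path(cameras_file).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            cam_id = int(parts[0])
            model = parts[1]
            width, height = int(parts[2]), int(parts[3])
            params = [float(p) for p in parts[4:]]
        except (IndexError, ValueError) as exc:
            raise SphereregError(
                f"{cameras_file}:{ln}: malformed camera line: {line!r}"
            ) from exc
        if model not in _SUPPORTED_MODELS:
            raise SphereregError(
                f"{cameras_file}:{ln}: unsupported camera model {model!r} "
                f"(supported: {', '.join(_SUPPORTED_MODELS)}; undistort upstream)"
            )
        if model == "PINHOLE":
            fx, fy, cx, cy = params
        else:  # SIMPLE_PINHOLE
            fx, cx, cy = params
            fy = fx
        intrinsics[cam_id] = (fx, fy, cx, cy, width, height)

    cameras: list[Camera] = []
    seen_ids: set[str] = set()
    # COLMAP images.txt has two lines per image; the second (2D points) may be
    # empty. Alternate pose/points lines, ignoring comments.
    pose_lines: list[tuple[int, str]] = []
    expecting_pose = True
    for ln, raw in enumerate(Path(images_file).read_text().splitlines(), 1):
        s = raw.strip()
        if s.startswith("#"):
            continue
        if expecting_pose:
            if not s:
                continue
            pose_lines.append((ln, s))
            expecting_pose = False
        else:
            expecting_pose = True  # points line (possibly empty) consumed
    for ln, line in pose_lines:
        parts = line.split()
        try:
            qw, qx, qy, qz = (float(p) for p in parts[1:5])
            tx, ty, tz = (float(p) for p in parts[5:8])
            cam_id = int(parts[8])
            name = parts[9] if len(parts) > 9 else parts[0]
        except (IndexError, ValueError) as exc:
            raise SphereregError(
                f"{images_file}:{ln}: malformed image line: {line!r}"
            ) from exc
        if name in seen_ids:
            raise SphereregError(f"{images_file}:{ln}: duplicate image id {name!r}")
        seen_ids.add(name)
        if cam_id not in intrinsics:
            raise SphereregError(
                f"{images_file}:{ln}: camera id {cam_id} not in {cameras_file}"
            )
        pose = RigidTransform.from_quaternion(
            (qw, qx, qy, qz), (tx, ty, tz), "W", "C"
        )
        fx, fy, cx, cy, w, h = intrinsics[cam_id]
        cameras.append(Camera(fx, fy, cx, cy, w, h, pose, camera_id=name))
    return cameras


def write_colmap_poses(
    cameras: list[Camera], cameras_file: str | Path, images_file: str | Path
) -> None:
    """Write cameras in the COLMAP text-model dialect (PINHOLE)."""
    cam_lines = ["# Camera list: CAMERA_ID MODEL WIDTH HEIGHT PARAMS[]"]
    img_lines = [
        "# Image list: IMAGE_ID QW QX QY QZ TX TY TZ CAMERA_ID NAME",
        "# (second line per image intentionally empty)",
    ]
    for k, cam in enumerate(cameras, start=1):
        cam_lines.append(
            f"{k} PINHOLE {cam.width} {cam.height} "
            f"{_fmt(cam.fx)} {_fmt(cam.fy)} {_fmt(cam.cx)} {_fmt(cam.cy)}"
        )
        q = cam.pose.quaternion_wxyz()
        t = cam.pose.translation
        name = cam.camera_id or f"image{k:04d}"
        img_lines.append(
            f"{k} {_fmt(q[0])} {_fmt(q[1])} {_fmt(q[2])} {_fmt(q[3])} "
            f"{_fmt(t[0])} {_fmt(t[1])} {_fmt(t[2])} {k} {name}"
        )
        img_lines.append("")
    Path(cameras_file).write_text("\n".join(cam_lines) + "\n")
    Path(images_file).write_text("\n".join(img_lines) + "\n")


# ---------------------------------------------------------------------------
# robot pose tables and hand-eye composition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoseTable:
    """Rows of (image_id, unit quaternion wxyz, translation) plus a frame
    convention tag (e.g. 'ee_to_base') and a source tag ('robot' or 'sfm')."""

    image_ids: list[str]
    quaternions: np.ndarray  # (n, 4) wxyz, unit norm
    translations: np.ndarray  # (n, 3)
    convention: str = "ee_to_base"
    source: str = "robot"

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternions, dtype=float).reshape(-1, 4)
        t = np.asarray(self.translations, dtype=float).reshape(-1, 3)
        if len(q) != len(self.image_ids) or len(t) != len(self.image_ids):
            raise SphereregError("pose table column lengths disagree")
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise SphereregError(
                f"row {bad}: quaternion norm {norms[bad]!r} is not 1 (tol 1e-9)"
            )
        if len(set(self.image_ids)) != len(self.image_ids):
            raise SphereregError("duplicate image ids in pose table")
        object.__setattr__(self, "quaternions", q)
        object.__setattr__(self, "translations", t)


def read_robot_poses(path: str | Path) -> PoseTable:
    """Read a delimited-text robot pose table.

    Format: comment/header lines starting with '#'; a required header
    ``# convention: <tag>`` (e.g. ee_to_base); data rows
    ``image_id qw qx qy qz tx ty tz`` (whitespace-delimited, mm).
    """
    convention = None
    ids, qs, ts = [], [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*convention\s*:\s*(\S+)", line)
            if m:
                convention = m.group(1)
            continue
        parts = line.split()
        if len(parts) != 8:
            raise SphereregError(f"{path}:{ln}: expected 8 fields, got {len(parts)}")
        try:
            q = [float(v) for v in parts[1:5]]
            t = [float(v) for v in parts[5:8]]
        except ValueError as exc:
            raise SphereregError(f"{path}:{ln}: non-numeric pose entry") from exc
        ids.append(parts[0])
        qs.append(q)
        ts.append(t)
    if convention is None:
        raise SphereregError(f"{path}: missing '# convention: <tag>' header")
    return PoseTable(ids, np.array(qs), np.array(ts), convention=convention)


def robot_to_camera_poses(
    table: PoseTable, hand_eye: RigidTransform
) -> list[RigidTransform]:
    """Compose end-effector poses with the hand-eye transform.

    ``table`` holds T_EE^B (end-effector in robot base, convention
    'ee_to_base'); ``hand_eye`` is T_C^EE (camera in end-effector frame).
    The camera-in-base pose is T_C^B = T_EE^B · T_C^EE; returned poses are
    world-to-camera with the robot base taken as the world frame W.
    """
    if table.convention != "ee_to_base":
        raise SphereregError(
            f"pose table convention {table.convention!r} != 'ee_to_base'"
        )
    if (hand_eye.frame_from, hand_eye.frame_to) != ("C", "EE"):
        raise SphereregError(
            f"hand-eye transform must map C -> EE, got "
            f"{hand_eye.frame_from!r} -> {hand_eye.frame_to!r}"
        )
    poses = []
    for k in range(len(table.image_ids)):
        T_EE_B = RigidTransform.from_quaternion(
            table.quaternions[k], table.translations[k], "EE", "B"
        )
        T_C_B = T_EE_B.compose(hand_eye)  # camera in base
        wc = T_C_B.inverse()  # base (world) to camera
        poses.append(RigidTransform(wc.rotation, wc.translation, 1.0, "W", "C"))
    return poses


# ---------------------------------------------------------------------------
# marker initialisations and reports
# ---------------------------------------------------------------------------


def read_marker_inits(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read labelled approximate marker centres: lines ``label x y z`` (mm)."""
    labels, centers = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise SphereregError(f"{path}:{ln}: expected 'label x y z'")
        try:
            centers.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise SphereregError(f"{path}:{ln}: non-numeric centre") from exc
        labels.append(parts[0])
    return labels, np.array(centers).reshape(-1, 3)


def write_marker_inits(path: str | Path, labels: list[str], centers: np.ndarray) -> None:
    lines = ["# label x y z (mm)"]
    for lab, c in zip(labels, centers):
        lines.append(f"{lab} {_fmt(c[0])} {_fmt(c[1])} {_fmt(c[2])}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_transform(path: str | Path, T: RigidTransform) -> None:
    """Write a transform as a 4x4 matrix plus scale, round-trippable."""
    lines = [
        f"# rigid/similarity transform {T.frame_from} -> {T.frame_to}",
        f"# scale: {_fmt(T.scale)}",
    ]
    for row in T.matrix:
        lines.append(" ".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_transform(path: str | Path, frame_from: str = "S", frame_to: str = "W") -> RigidTransform:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(v) for v in line.split()])
    M = np.array(rows)
    if M.shape != (4, 4):
        raise SphereregError(f"{path}: expected a 4x4 matrix, got {M.shape}")
    return RigidTransform.from_matrix(M, frame_from, frame_to)


def write_registration_report(
    path: str | Path, result: RegistrationResult, diagnostics: dict | None = None
) -> None:
    lines = [
        "# scene registration report",
        f"converged: {result.converged}",
        f"n_iterations: {result.n_iterations}",
        f"scale: {_fmt(result.scale)}",
        f"initial_cost: {_fmt(result.initial_cost)}",
        f"final_cost: {_fmt(result.final_cost)}",
        "per_image_rms_residual: "
        + " ".join(_fmt(v) for v in result.per_image_rms_residual),
    ]
    if diagnostics:
        lines.append(f"init_image: {diagnostics.get('init_image')}")
        for entry in diagnostics.get("match_log", []):
            lines.append(f"match_log: {entry}")
    Path(path).write_text("\n".join(lines) + "\n")
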