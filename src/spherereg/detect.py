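"""Detection of elliptical marker silhouettes in grayscale images.

Pipeline: global threshold (Otsu by default, so detection is invariant to
affine intensity changes) -> connected components -> sub-pixel boundary
extraction with marching squares at the threshold level -> direct
least-squares conic fit constrained to ellipses (Fitzgibbon/Halir-Flusser)
-> geometric residual gating. Merged or partially occluded blobs whose
boundary deviates from the fitted ellipse are rejected by the gate, which is
the desired behaviour for registration: a missing marker observation is
harmless, a corrupted one is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .exceptions import DegenerateConicError, SphereregError
from .geometry import Camera, Conic, SphereMarker
from .observations import EllipseDetection, ObservationSet
from .register import PNP_GATE_PX, PNP_GATE_REFERENCE_WIDTH
from .transforms import RigidTransform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable knobs of the silhouette detector.

    polarity : markers brighter ('bright') or darker ('dark') than background.
    threshold : fixed intensity threshold in [0, 1]; None selects Otsu on the
        min-max normalised image (adaptive, gain/offset invariant).
    min_axis_px : reject ellipses with semi-minor axis below this (noise specks).
    max_axis_px : reject above this; None means a quarter of the image diagonal.
    max_rms_edge_px : gate on the RMS foot-point distance of the boundary
        points to the fitted ellipse; rejects merged/occluded blobs.
    n_outline_points : parametric samples stored per detection.
    """

    polarity: str = "bright"
    threshold: float | None = None
    min_axis_px: float = 10.0
    max_axis_px: float | None = None
    max_rms_edge_px: float = 0.5
    n_outline_points: int = 20

    def __post_init__(self) -> None:
        if self.polarity not in ("bright", "dark"):
            raise SphereregError(f"polarity must be bright|dark, got {self.polarity!r}")


def fit_ellipse_conic(points: np.ndarray) -> Conic:
    """Direct least-squares conic fit constrained to ellipses.

    Halir & Flusser's numerically stable partitioning of Fitzgibbon's method:
    the constraint 4AC - B^2 = 1 guarantees the solution is an ellipse.
    Points are centred/scaled before fitting for conditioning.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(p) < 5:
        raise SphereregError(f"ellipse fit needs >= 5 points, got {len(p)}")
    mean = p.mean(axis=0)
    scale = max(p.std(), 1e-12)
    q = (p - mean) / scale
    x, y = q[:, 0], q[:, 1]
    D1 = np.stack([x * x, x * y, y * y], axis=1)
    D2 = np.stack([x, y, np.ones_like(x)], axis=1)
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConicError("degenerate point configuration") from exc
    Mmat = S1 + S2 @ T
    C1inv = np.array([[0, 0, 0.5], [0, -1.0, 0], [0.5, 0, 0]])
    Mred = C1inv @ Mmat
    w, V = np.linalg.eig(Mred)
    # admissible eigenvector: 4 a c - b^2 > 0
    cond = np.real(4 * V[0] * V[2] - V[1] ** 2)
    ok = np.isreal(w) & (cond > 0)
    if not ok.any():
        raise DegenerateConicError("no elliptical solution for these points")
    a1 = np.real(V[:, np.argmax(ok)])
    a2 = T @ a1
    A, B, C = a1
    D, E, F = a2
    # undo the normalisation: x = (X - mx)/s etc.
    s, mx, my = scale, mean[0], mean[1]
    M = np.array(
        [
            [A / s**2, B / (2 * s**2), (D / (2 * s) - (2 * A * mx + B * my) / (2 * s**2))],
            [B / (2 * s**2), C / s**2, (E / (2 * s) - (2 * C * my + B * mx) / (2 * s**2))],
            [0.0, 0.0, 0.0],
        ]
    )
    M[2, 0] = M[0, 2]
    M[2, 1] = M[1, 2]
    M[2, 2] = (
        A * mx**2 / s**2
        + B * mx * my / s**2
        + C * my**2 / s**2
        - D * mx / s
        - E * my / s
        + F
    )
    return Conic(M)


def detect_ellipses(
    image: np.ndarray, config: DetectionConfig | None = None
) -> list[EllipseDetection]:
    """Detect elliptical marker silhouettes in a single-channel image.

    Returns detections sorted by descending pixel support. An image with no
    acceptable ellipse yields an empty list (not an error).
    """
    from .metrics import point_ellipse_distance

    cfg = config or DetectionConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise SphereregError(f"expected a 2D intensity image, got shape {img.shape}")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return []
    img = (img - lo) / (hi - lo)
    if cfg.polarity == "dark":
        img = 1.0 - img
    if cfg.threshold is None:
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(img))
    else:
        thr = float(cfg.threshold)
    binary = img > thr
    labels = measure.label(binary)
    max_axis = (
        cfg.max_axis_px
        if cfg.max_axis_px is not None
        else 0.25 * float(np.hypot(*img.shape))
    )

    detections: list[EllipseDetection] = []
    for region in measure.regionprops(labels):
        if region.area < np.pi * cfg.min_axis_px**2 * 0.25:
            continue
        r0, c0, r1, c1 = region.bbox
        pad = 2
        r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
        r1p, c1p = min(r1 + pad, img.shape[0]), min(c1 + pad, img.shape[1])
        sub = np.where(
            labels[r0p:r1p, c0p:c1p] == region.label, img[r0p:r1p, c0p:c1p], 0.0
        )
        contours = measure.find_contours(sub, level=thr)
        if not contours:
            continue
        contour = max(contours, key=len)
        # find_contours returns (row, col); convert to pixel (x, y)
        edge = np.stack([contour[:, 1] + c0p, contour[:, 0] + r0p], axis=1)
        if len(edge) < 5:
            continue
        try:
            conic = fit_ellipse_conic(edge)
            center, (a, b), _ = conic.params()
        except DegenerateConicError:
            continue
        if b < cfg.min_axis_px or a > max_axis:
            logger.debug("detection rejected by axis gates: a=%.1f b=%.1f", a, b)
            continue
        rms = float(np.sqrt(np.mean(point_ellipse_distance(conic, edge) ** 2)))
        if rms > cfg.max_rms_edge_px:
            logger.info(
                "detection at %s rejected: boundary RMS %.2f px > %.2f px "
                "(merged or occluded blob?)", center.round(1), rms, cfg.max_rms_edge_px,
            )
            continue
        detections.append(
            EllipseDetection(
                conic=conic,
                outline_points=conic.sample_outline(cfg.n_outline_points),
                support_pixel_count=int(region.area),
                image_id="",
                edge_points=edge,
            )
        )
    detections.sort(key=lambda d: -d.support_pixel_count)
    return detections


def match_detections_across_images(
    detections_per_image: list[list[EllipseDetection]],
    cameras: list[Camera],
    markers: list[SphereMarker],
    T_init: RigidTransform,
    gate_px: float | None = None,
    outline_source: str = "edge",
) -> tuple[ObservationSet, list[str]]:
    """Associate detections with markers given an initial registration.

    Each detection is assigned to the marker whose projected centre (under
    ``T_init``) is nearest within the gate; when two detections compete for a
    marker the nearer one wins and the conflict is logged. Unassigned
    detections are dropped. ``outline_source`` selects which points feed the
    refinement: raw sub-pixel 'edge' points when available, else 'fitted'
    parametric samples.
    """
    if outline_source not in ("edge", "fitted"):
        raise SphereregError(f"outline_source must be edge|fitted, got {outline_source!r}")
    log: list[str] = []
    entries: dict[tuple[int, int], np.ndarray] = {}
    markers_W = [m.transformed(T_init) for m in markers]
    for i, (cam, dets) in enumerate(zip(cameras, detections_per_image)):
        gate = (
            gate_px
            if gate_px is not None
            else PNP_GATE_PX * cam.width / PNP_GATE_REFERENCE_WIDTH
        )
        proj = np.full((len(markers), 2), np.nan)
        for j, mw in enumerate(markers_W):
            cc = cam.pose.apply(mw.center)
            if cc[2] > mw.radius:
                proj[j] = cam.project_points(mw.center)
        assigned: dict[int, tuple[float, int]] = {}  # marker -> (dist, det idx)
        for k, det in enumerate(dets):
            ctr = det.center
            dist = np.linalg.norm(proj - ctr, axis=1)
            if np.all(~np.isfinite(dist)):
                continue
            j = int(np.nanargmin(dist))
            if not np.isfinite(dist[j]) or dist[j] > gate:
                log.append(f"image {i}: detection {k} at {ctr.round(1)} unmatched, dropped")
                continue
            if j in assigned and assigned[j][0] <= dist[j]:
                log.append(
                    f"image {i}: detections {assigned[j][1]} and {k} compete for "
                    f"marker {j}; kept {assigned[j][1]} (nearer)"
                )
                continue
            if j in assigned:
                log.append(
                    f"image {i}: detections {assigned[j][1]} and {k} compete for "
                    f"marker {j}; kept {k} (nearer)"
                )
            assigned[j] = (float(dist[j]), k)
        for j, (_, k) in assigned.items():
            det = dets[k]
            pts = (
                det.edge_points
                if outline_source == "edge" and det.edge_points is not None
                else det.outline_points
            )
            entries[(i, j)] = pts
    obs = ObservationSet(cameras, markers, entries)
    return obs, log
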