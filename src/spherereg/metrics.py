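"""Accuracy metrics for sphere-based scene registration.

* **Radial error** (mm): deviation from tangency of a viewing ray. A pixel on
  the detected silhouette outline of a marker back-projects to a ray that, for
  a perfect registration, grazes the sphere: the perpendicular distance d from
  the ray to the sphere centre equals the radius. The metric is |d - r|. (A
  secant ray counts its tangency deficit, not its zero set-distance to the
  surface.)
* **Reprojection error** (px): symmetric mean geometric distance between two
  ellipses — points sampled on each ellipse, orthogonal (foot-point) distance
  to the other, averaged over both directions.
* **Chamfer distance** (mm): symmetric mean nearest-surface distance between
  two triangulated meshes, estimated with area-uniform surface sampling and
  exact point-to-triangle distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DegenerateConicError, SphereregError
from .geometry import Camera, Conic, SphereMarker
from .markers import SurfaceMesh
from .observations import ObservationSet
from .register import RegistrationResult

# ---------------------------------------------------------------------------
# radial error
# ---------------------------------------------------------------------------


def radial_error(
    outline_points: np.ndarray, cam: Camera, marker: SphereMarker
) -> np.ndarray:
    """|perpendicular ray-to-centre distance - radius| in mm, per pixel point.

    ``marker`` must be expressed in the camera's world frame and lie in front
    of the camera.
    """
    pts = np.atleast_2d(np.asarray(outline_points, dtype=float))
    origin, dirs = cam.back_project_rays(pts)
    oc = marker.center - origin
    along = dirs @ oc
    if np.any(along <= 0):
        raise SphereregError("marker is behind the camera for some rays")
    perp = np.linalg.norm(oc[None, :] - along[:, None] * dirs, axis=1)
    return np.abs(perp - marker.radius)


@dataclass(frozen=True)
class RadialErrorReport:
    """Radial errors aggregated per point, per marker and per image."""

    errors_mm: np.ndarray  # all per-point errors, stacked
    point_marker: np.ndarray  # marker index per point
    point_image: np.ndarray  # image index per point

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.errors_mm))

    @property
    def median_mm(self) -> float:
        return float(np.median(self.errors_mm))

    def per_marker_mean(self) -> dict[int, float]:
        return {
            int(j): float(self.errors_mm[self.point_marker == j].mean())
            for j in np.unique(self.point_marker)
        }

    def per_image_mean(self) -> dict[int, float]:
        return {
            int(i): float(self.errors_mm[self.point_image == i].mean())
            for i in np.unique(self.point_image)
        }

    @property
    def n_points(self) -> int:
        return len(self.errors_mm)


def evaluate_registration(
    result: RegistrationResult, control_obs: ObservationSet
) -> RadialErrorReport:
    """Radial errors of control-marker outlines under an estimated registration.

    The control markers (held out of the registration) are mapped from the
    scan frame into the world frame with ``result.transform`` and every stored
    outline point contributes one radial error.
    """
    if not control_obs.entries:
        raise SphereregError("control observation set is empty")
    errs, mk, im = [], [], []
    markers_W = [m.transformed(result.transform) for m in control_obs.markers]
    for (i, j), pts in sorted(control_obs.entries.items()):
        e = radial_error(pts, control_obs.cameras[i], markers_W[j])
        errs.append(e)
        mk.append(np.full(len(e), j))
        im.append(np.full(len(e), i))
    return RadialErrorReport(
        np.concatenate(errs), np.concatenate(mk), np.concatenate(im)
    )


# ---------------------------------------------------------------------------
# point-to-ellipse (foot-point) distance and reprojection error
# ---------------------------------------------------------------------------


def _dist_to_aligned_ellipse(a: float, b: float, q: np.ndarray) -> np.ndarray:
    """Orthogonal distance from points ``q`` to the axis-aligned ellipse
    x^2/a^2 + y^2/b^2 = 1 (a >= b > 0). Robust bisection on the radial
    Lagrange parameter; exact for circles and on-axis points."""
    y0 = np.abs(q[:, 0])
    y1 = np.abs(q[:, 1])
    d = np.empty(len(q))

    on_x_axis = y1 == 0.0
    gen = ~on_x_axis
    # points on the major axis: closest point may be off-axis inside the evolute
    if on_x_axis.any():
        x0 = y0[on_x_axis]
        if a > b:
            xe = (a * a - b * b) / a  # evolute cusp on the major axis
            inner = x0 < xe
            dx = np.empty(len(x0))
            xc = a * a * x0[inner] / (a * a - b * b)
            yc = b * np.sqrt(np.maximum(1.0 - (xc / a) ** 2, 0.0))
            dx[inner] = np.hypot(xc - x0[inner], yc)
            dx[~inner] = np.abs(x0[~inner] - a)
        else:
            dx = np.abs(x0 - a)
        d[on_x_axis] = dx
    if gen.any():
        gy0 = y0[gen]
        gy1 = y1[gen]
        # F(t) = (a y0 / (t + a^2))^2 + (b y1 / (t + b^2))^2 - 1, strictly
        # decreasing on (-b^2, inf) with a unique root
        lo = -b * b + b * gy1
        hi = np.maximum(lo, np.hypot(a * gy0, b * gy1) - min(a, b) ** 2) + a * a
        # expand hi until F(hi) < 0
        for _ in range(60):
            F = (a * gy0 / (hi + a * a)) ** 2 + (b * gy1 / (hi + b * b)) ** 2 - 1.0
            if np.all(F < 0):
                break
            hi = np.where(F >= 0, hi * 2 + 1.0, hi)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            F = (a * gy0 / (mid + a * a)) ** 2 + (b * gy1 / (mid + b * b)) ** 2 - 1.0
            lo = np.where(F > 0, mid, lo)
            hi = np.where(F > 0, hi, mid)
        t = 0.5 * (lo + hi)
        xc = a * a * gy0 / (t + a * a)
        yc = b * b * gy1 / (t + b * b)
        d[gen] = np.hypot(xc - gy0, yc - gy1)
    return d


def point_ellipse_distance(conic: Conic, points: np.ndarray) -> np.ndarray:
    """Orthogonal (foot-point) distance in px from pixel points to an ellipse."""
    if not conic.is_ellipse:
        raise DegenerateConicError("foot-point distance needs a real ellipse")
    center, (a, b), phi = conic.params()
    p = np.atleast_2d(np.asarray(points, dtype=float)) - center
    ca, sa = np.cos(phi), np.sin(phi)
    q = np.stack([p[:, 0] * ca + p[:, 1] * sa, -p[:, 0] * sa + p[:, 1] * ca], axis=1)
    return _dist_to_aligned_ellipse(a, b, q)


def reprojection_error(
    projected: Conic, detected: Conic, n_samples: int = 100
) -> float:
    """Symmetric mean geometric distance (px) between two ellipses."""
    pa = projected.sample_outline(n_samples)
    pb = detected.sample_outline(n_samples)
    d_ab = point_ellipse_distance(detected, pa).mean()
    d_ba = point_ellipse_distance(projected, pb).mean()
    return float(0.5 * (d_ab + d_ba))


# ---------------------------------------------------------------------------
# Chamfer distance between meshes
# ---------------------------------------------------------------------------


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from each point to its paired triangle.

    ``points``: (n, 3); ``tri``: (n, 3, 3). Barycentric-clamping algorithm,
    fully vectorised.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        closest[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vc = d1 * d4 - d3 * d2
    v_ab = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    w_ac = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    w_bc = np.divide(
        d4 - d3, denom_bc, out=np.zeros_like(d4), where=denom_bc != 0
    )
    assign(
        (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
        b + w_bc[:, None] * (c - b),
    )  # edge BC

    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    interior = a + v[:, None] * ab + w[:, None] * ac
    closest[~done] = interior[~done]
    return np.linalg.norm(points - closest, axis=1)


def point_mesh_distance(
    points: np.ndarray, mesh: SurfaceMesh, n_candidates: int = 32
) -> np.ndarray:
    """Distance from points to a triangulated surface.

    Candidate triangles are pruned with a KD-tree on triangle centroids
    (``n_candidates`` nearest per query point), then scored exactly. Accurate
    whenever triangles are small relative to feature spacing, which holds for
    scanner-resolution meshes.
    """
    if len(mesh.faces) == 0:
        # degenerate: point cloud only
        tree = cKDTree(mesh.vertices)
        return tree.query(points)[0]
    tris = mesh.vertices[mesh.faces]  # (m, 3, 3)
    centroids = tris.mean(axis=1)
    k = min(n_candidates, len(tris))
    tree = cKDTree(centroids)
    out = np.empty(len(points))
    chunk = 20000
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]
        _, idx = tree.query(p, k=k)
        idx = np.atleast_2d(idx)
        p_rep = np.repeat(p, k, axis=0)
        d = _point_triangle_distances(p_rep, tris[idx.ravel()])
        out[s : s + chunk] = d.reshape(len(p), k).min(axis=1)
    return out


def chamfer_distance(
    a: SurfaceMesh,
    b: SurfaceMesh,
    n_samples: int = 100_000,
    statistic: str = "mean",
    symmetric: bool = True,
    seed: int = 0,
) -> float:
    """Chamfer distance (mm) between two surfaces in the same frame.

    Samples ``n_samples`` points area-uniformly on each mesh, computes each
    sample's exact nearest distance to the *other* mesh's surface, and reduces
    with ``statistic`` (mean | median | rms). ``symmetric`` averages the two
    directions; one-sided uses only a -> b.
    """
    import trimesh

    if a.n_vertices == 0 or b.n_vertices == 0:
        raise SphereregError("chamfer distance needs non-empty meshes")
    if a.frame != b.frame:
        raise SphereregError(
            f"meshes live in different frames {a.frame!r} vs {b.frame!r}"
        )
    reducers = {
        "mean": np.mean,
        "median": np.median,
        "rms": lambda x: np.sqrt(np.mean(np.square(x))),
    }
    if statistic not in reducers:
        raise SphereregError(f"unknown statistic {statistic!r}")
    red = reducers[statistic]

    def one_sided(src: SurfaceMesh, dst: SurfaceMesh, s: int) -> float:
        tm = trimesh.Trimesh(src.vertices, src.faces, process=False)
        pts, _ = trimesh.sample.sample_surface(tm, n_samples, seed=s)
        return float(red(point_mesh_distance(np.asarray(pts), dst)))

    # the same seed drives both directions so chamfer(a, b) == chamfer(b, a)
    # exactly, not just in expectation
    d_ab = one_sided(a, b, seed)
    if not symmetric:
        return d_ab
    d_ba = one_sided(b, a, seed)
    return 0.5 * (d_ab + d_ba)
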