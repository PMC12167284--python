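"""Scene registration: recover the scan-to-world transform from sphere images.

Two stages, mirroring the standard two-stage design for conic-based pose
estimation:

1. **Correspondence + initial pose** (:func:`init_registration_pnp`): in one
   image where all markers are visible, exhaustively match 4-subsets of the
   detected ellipse centres against ordered 4-tuples of the M sphere centres,
   solving the minimal Perspective-3-Point problem for each hypothesis (the
   4th pair disambiguates the up-to-4 P3P roots) and scoring hypotheses by how
   many of the remaining markers project within a gating radius of some
   detected centre. Ellipse centres are biased estimates of projected sphere
   centres (perspective offset), which the gate absorbs; the bias never enters
   stage 2.

2. **Refinement** (:func:`refine_registration`): Levenberg–Marquardt on the
   bilinear conic residual x^T E x summed over all images, markers and outline
   points, where E is the silhouette conic of the marker mapped by the current
   transform. Conics are normalised (unit Frobenius, positive 2x2-trace) so
   the algebraic cost cannot be deflated by conic scale. In ``similarity``
   mode a global scale is estimated jointly — needed when camera poses come
   from structure-from-motion and are metrically undetermined; the scale is
   placed on the scan-to-world map (c_W = s R c_S + t, radii scaled to s r),
   which is algebraically equivalent to scaling the camera poses but keeps
   them fixed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import InitializationError, SphereregError
from .geometry import Camera, Conic, SphereMarker
from .observations import EllipseDetection, ObservationSet
from .transforms import RigidTransform

logger = logging.getLogger(__name__)

#: PnP inlier gate at the full-frame reference width (scaled with image width)
PNP_GATE_PX = 25.0
PNP_GATE_REFERENCE_WIDTH = 9504.0


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of the conic-residual minimisation."""

    transform: RigidTransform  # S -> W; carries the estimated scale
    scale: float
    initial_cost: float
    final_cost: float
    per_image_rms_residual: np.ndarray
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.final_cost > self.initial_cost * (1 + 1e-12) + 1e-300:
            raise SphereregError(
                "internal error: accepted refinement increased the cost"
            )


# ---------------------------------------------------------------------------
# P3P (Grunert) — batched over correspondence hypotheses
# ---------------------------------------------------------------------------


def _p3p_grunert(bearings: np.ndarray, world: np.ndarray) -> np.ndarray:
    """Minimal P3P for a batch of world-point triples sharing bearing vectors.

    Parameters
    ----------
    bearings : (3, 3) array
        Unit viewing directions f1, f2, f3 in the camera frame.
    world : (K, 3, 3) array
        K triples of 3D points (one row per point).

    Returns
    -------
    (K, 4, 3, 4) array of candidate [R | t] camera-from-world poses; invalid
    slots are NaN. Up to 4 real solutions per hypothesis (Grunert's quartic).

    The quartic in v = s3/s1 is assembled by exact polynomial arithmetic from
    the two ratio equations of the law-of-cosines system, which avoids
    transcribing the classical closed-form coefficients.
    """
    f1, f2, f3 = bearings
    cos_a = float(f2 @ f3)  # angle opposite P1
    cos_b = float(f1 @ f3)  # angle opposite P2
    cos_g = float(f1 @ f2)  # angle opposite P3
    K = len(world)
    a2 = np.sum((world[:, 1] - world[:, 2]) ** 2, axis=1)
    b2 = np.sum((world[:, 0] - world[:, 2]) ** 2, axis=1)
    c2 = np.sum((world[:, 0] - world[:, 1]) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ka = (a2 - c2) / b2
        Kc = c2 / b2

    # u = N(v) / D(v):  N quadratic in v, D linear (same D for all hypotheses)
    # N = (Ka-1) v^2 - 2 Ka cos_b v + (Ka+1);  D = -2 cos_a v + 2 cos_g
    N = np.stack([Ka - 1.0, -2.0 * Ka * cos_b, Ka + 1.0], axis=1)  # (K, 3) desc
    D = np.array([-2.0 * cos_a, 2.0 * cos_g])  # (2,) descending

    def conv(p, q):
        # polynomial product for stacked descending-coefficient arrays
        lp, lq = p.shape[-1], q.shape[-1]
        out = np.zeros(p.shape[:-1] + (lp + lq - 1,))
        for i in range(lp):
            for j in range(lq):
                out[..., i + j] += p[..., i] * q[..., j]
        return out

    NN = conv(N, N)  # (K, 5)
    ND = conv(N, D[None, :].repeat(K, axis=0))  # (K, 4)
    G = np.stack(
        [-Kc, 2.0 * Kc * cos_b, 1.0 - Kc], axis=1
    )  # 1 - Kc(1 + v^2 - 2 v cos_b)
    DD = conv(D[None], D[None])[0]  # (3,)
    GDD = conv(G, DD[None, :].repeat(K, axis=0))  # (K, 5)
    quartic = NN.copy()
    quartic[:, 1:] -= 2.0 * cos_g * ND
    quartic += GDD  # (K, 5) descending coefficients

    # roots via batched companion-matrix eigenvalues
    lead = quartic[:, 0]
    ok = np.abs(lead) > 1e-14 * np.abs(quartic).max(axis=1)
    mono = np.where(ok[:, None], quartic / np.where(ok, lead, 1.0)[:, None], 0.0)
    # companion for v^4 + p1 v^3 + p2 v^2 + p3 v + p4: first row -p1..-p4
    comp = np.zeros((K, 4, 4))
    comp[:, 0, :] = -mono[:, 1:]
    comp[:, 1:, :3] = np.eye(3)
    roots = np.linalg.eigvals(comp)  # (K, 4)
    real = np.abs(roots.imag) < 1e-7 * (1.0 + np.abs(roots.real))
    v = np.where(real & (roots.real > 1e-12) & ok[:, None], roots.real, np.nan)

    # distances s1, s2, s3 from each admissible root
    denom_u = -2.0 * cos_a * v + 2.0 * cos_g
    Nv = (Ka[:, None] - 1.0) * v**2 - 2.0 * Ka[:, None] * cos_b * v + (Ka[:, None] + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = Nv / denom_u
        s1sq = b2[:, None] / (1.0 + v**2 - 2.0 * v * cos_b)
        s1 = np.sqrt(np.where(s1sq > 0, s1sq, np.nan))
    s2 = u * s1
    s3 = v * s1
    valid = np.isfinite(s1) & (s2 > 0) & (s3 > 0)

    # absolute orientation (world -> camera) from the 3 ranged points
    poses = np.full((K, 4, 3, 4), np.nan)
    F = bearings  # (3, 3) rows
    wc = world.mean(axis=1, keepdims=True)  # (K, 1, 3)
    w0 = world - wc
    for r in range(4):
        m = valid[:, r]
        if not m.any():
            continue
        S = np.stack([s1[m, r], s2[m, r], s3[m, r]], axis=1)  # (k, 3)
        X = S[:, :, None] * F[None, :, :]  # camera-frame points (k, 3, 3)
        xc = X.mean(axis=1, keepdims=True)
        x0 = X - xc
        H = np.einsum("kij,kil->kjl", w0[m], x0)  # world-to-cam covariance
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(np.einsum("kij,kjl->kil", U, Vt)))
        Dm = np.zeros((m.sum(), 3, 3))
        Dm[:, 0, 0] = 1.0
        Dm[:, 1, 1] = 1.0
        Dm[:, 2, 2] = d
        Rk = np.einsum("kij,kjl,klm->kmi", U, Dm, Vt)  # R = V D U^T
        tk = xc[:, 0, :] - np.einsum("kij,kj->ki", Rk, wc[m][:, 0, :])
        poses[m, r, :, :3] = Rk
        poses[m, r, :, 3] = tk
    return poses


def _pixels_to_bearings(cam: Camera, pixels: np.ndarray) -> np.ndarray:
    d = np.stack(
        [
            (pixels[:, 0] - cam.cx) / cam.fx,
            (pixels[:, 1] - cam.cy) / cam.fy,
            np.ones(len(pixels)),
        ],
        axis=1,
    )
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def init_registration_pnp(
    ellipse_centers: np.ndarray,
    cam: Camera,
    markers: list[SphereMarker],
    gate_px: float | None = None,
) -> RigidTransform:
    """Exhaustive correspondence search + minimal PnP in a single image.

    Every 4-subset of the detected ellipse centres is paired with every
    ordered choice of 4 of the M sphere centres; each hypothesis is solved
    with P3P (4th pair disambiguates) and scored by the number of remaining
    markers whose projection falls within the gate of an unassigned detected
    centre. Subsets are visited in input order with an early exit once a
    hypothesis explains all markers. Deterministic tie-break: highest inlier
    count, then lowest summed gated distance, then assignment order.

    Returns the scan-to-world transform T_S^W obtained through the known
    camera pose. Raises :class:`InitializationError` if no hypothesis reaches
    M/2 inliers.
    """
    centers = np.asarray(ellipse_centers, dtype=float).reshape(-1, 2)
    n_det = len(centers)
    M = len(markers)
    if n_det < 4:
        raise SphereregError(f"need >= 4 ellipse centres for PnP init, got {n_det}")
    if M < 4:
        raise SphereregError(f"need >= 4 markers for PnP init, got {M}")
    if gate_px is None:
        gate_px = PNP_GATE_PX * cam.width / PNP_GATE_REFERENCE_WIDTH
    sphere_centers = np.array([m.center for m in markers])
    assignments = np.array(list(itertools.permutations(range(M), 4)))  # ordered
    world_all = sphere_centers[assignments]  # (K, 4, 3)

    best = None  # (score, sum_gated_dist, order, Rt)
    order_counter = 0
    for subset in itertools.combinations(range(n_det), 4):
        sub = np.array(subset)
        bearings = _pixels_to_bearings(cam, centers[sub])
        poses = _p3p_grunert(bearings[:3], world_all[:, :3, :])  # (K, 4, 3, 4)

        # disambiguate with the 4th correspondence
        flat = poses.reshape(-1, 3, 4)
        valid = np.isfinite(flat[:, 0, 0])
        p4 = world_all[:, 3, :].repeat(4, axis=0)
        Xc4 = np.einsum("kij,kj->ki", flat[:, :, :3], p4) + flat[:, :, 3]
        front = Xc4[:, 2] > 0
        px4 = np.stack(
            [
                cam.fx * Xc4[:, 0] / Xc4[:, 2] + cam.cx,
                cam.fy * Xc4[:, 1] / Xc4[:, 2] + cam.cy,
            ],
            axis=1,
        )
        err4 = np.linalg.norm(px4 - centers[sub[3]], axis=1)
        err4 = np.where(valid & front, err4, np.inf)
        err4_k = err4.reshape(-1, 4)
        best_root = np.argmin(err4_k, axis=1)
        kidx = np.arange(len(err4_k))
        cand = poses[kidx, best_root]  # (K, 3, 4)
        cand_ok = np.isfinite(err4_k[kidx, best_root]) & (
            err4_k[kidx, best_root] < gate_px
        )
        if not cand_ok.any():
            order_counter += len(assignments)
            continue

        # score candidates: project all markers, count gated matches
        ck = cand[cand_ok]
        Xc = np.einsum("kij,mj->kmi", ck[:, :, :3], sphere_centers) + ck[:, None, :, 3]
        with np.errstate(divide="ignore", invalid="ignore"):
            px = np.stack(
                [
                    cam.fx * Xc[..., 0] / Xc[..., 2] + cam.cx,
                    cam.fy * Xc[..., 1] / Xc[..., 2] + cam.cy,
                ],
                axis=-1,
            )
        dist = np.linalg.norm(px[:, :, None, :] - centers[None, None, :, :], axis=-1)
        dist = np.where(Xc[..., 2:3] > 0, dist, np.inf)  # (k, M, n_det)
        nearest = dist.min(axis=2)  # (k, M)
        inlier = nearest < gate_px
        score = inlier.sum(axis=1)
        gsum = np.where(inlier, nearest, 0.0).sum(axis=1)

        k_best = int(np.lexsort((gsum, -score))[0])
        entry = (
            int(score[k_best]),
            float(gsum[k_best]),
            order_counter + int(np.flatnonzero(cand_ok)[k_best]),
            ck[k_best],
        )
        if best is None or (-entry[0], entry[1], entry[2]) < (-best[0], best[1], best[2]):
            best = entry
        order_counter += len(assignments)
        if best is not None and best[0] == M:
            break  # every marker explained; cannot do better

    if best is None or best[0] < M / 2:
        raise InitializationError(
            "initialization failed; choose an image with all markers well visible"
        )
    score, _, _, Rt = best
    logger.info("PnP init: %d/%d markers explained within %.1f px", score, M, gate_px)
    T_S_C = RigidTransform(Rt[:, :3], Rt[:, 3], 1.0, markers[0].frame, "C")
    cam_pose = RigidTransform(
        cam.pose.rotation, cam.pose.translation, 1.0, cam.pose.frame_from, "C"
    )
    return cam_pose.inverse().compose(T_S_C)


# ---------------------------------------------------------------------------
# Levenberg–Marquardt refinement of the conic bilinear cost
# ---------------------------------------------------------------------------


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float
    )


class _Objective:
    """Vectorised residuals/Jacobian of sum ||x^T E_ij x||^2 over outline points."""

    def __init__(self, obs: ObservationSet, mode: str):
        self.mode = mode
        self.n_params = 7 if mode == "similarity" else 6
        img_idx, mrk_idx, point_pair, points = obs.stacked()
        self.img_idx, self.mrk_idx = img_idx, mrk_idx
        self.point_pair = point_pair
        self.xh = np.concatenate([points, np.ones((len(points), 1))], axis=1)
        # per-pair camera data; the conic is evaluated in the numerically
        # benign form E ∝ K^-T (c c^T - (|c|^2 - r^2) I) K^-1 (see geometry)
        self.Kinv = np.stack(
            [np.linalg.inv(obs.cameras[i].K) for i in img_idx]
        )
        self.Rcam = np.stack([obs.cameras[i].pose.rotation for i in img_idx])
        self.tcam = np.stack([obs.cameras[i].pose.translation for i in img_idx])
        self.centers_S = np.stack([obs.markers[j].center for j in mrk_idx])
        self.radii = np.array([obs.markers[j].radius for j in mrk_idx])
        self.n_pairs = len(img_idx)
        self._eye = np.broadcast_to(np.eye(3), (self.n_pairs, 3, 3))

    def _state(self, R, t, s):
        cW = s * self.centers_S @ R.T + t
        c = np.einsum("pij,pj->pi", self.Rcam, cW) + self.tcam  # camera frame
        rW2 = (s * self.radii) ** 2
        inner = np.einsum("pi,pj->pij", c, c) - (
            np.sum(c * c, axis=1) - rW2
        )[:, None, None] * self._eye
        E_u = np.einsum("pji,pjk,pkl->pil", self.Kinv, inner, self.Kinv)
        tr = E_u[:, 0, 0] + E_u[:, 1, 1]
        sign = np.where(tr >= 0, 1.0, -1.0)
        norm = np.linalg.norm(E_u, axis=(1, 2))
        E_hat = E_u * (sign / norm)[:, None, None]
        return E_hat, E_u, c, sign, norm

    def conics(self, R, t, s):
        """Normalised conic stack E_ij (npair, 3, 3) for the current state."""
        return self._state(R, t, s)[0]

    def residuals(self, R, t, s):
        E_hat = self.conics(R, t, s)
        return np.einsum("ni,nij,nj->n", self.xh, E_hat[self.point_pair], self.xh)

    def residuals_and_jacobian(self, R, t, s):
        E_hat, E_u, c, sign, norm = self._state(R, t, s)
        r = np.einsum("ni,nij,nj->n", self.xh, E_hat[self.point_pair], self.xh)

        # dc_W / dparams: omega (right-composed axis-angle), t, log s
        npar = self.n_params
        dcW = np.zeros((self.n_pairs, 3, npar))
        sR = s * R
        for p in range(self.n_pairs):
            dcW[p, :, :3] = -sR @ _skew(self.centers_S[p])
        dcW[:, :, 3:6] = np.eye(3)
        if npar == 7:
            dcW[:, :, 6] = s * self.centers_S @ R.T
        dc = np.einsum("pij,pjq->piq", self.Rcam, dcW)  # camera-frame centre

        d_inner = (
            np.einsum("piq,pj->pijq", dc, c)
            + np.einsum("pi,pjq->pijq", c, dc)
            - 2.0
            * np.einsum("pk,pkq->pq", c, dc)[:, None, None, :]
            * self._eye[..., None]
        )
        if npar == 7:
            # d(r_W^2)/d log s = 2 r_W^2 enters the isotropic part with +
            d_inner[..., 6] += (
                2.0 * (s * self.radii) ** 2
            )[:, None, None] * self._eye

        dE_u = np.einsum(
            "pji,pjkq,pkl->pilq", self.Kinv, d_inner, self.Kinv
        )
        Ebar = E_u / norm[:, None, None]
        coef = np.einsum("pij,pijq->pq", Ebar, dE_u)
        dE_hat = (
            dE_u - np.einsum("pij,pq->pijq", Ebar, coef)
        ) * (sign / norm)[:, None, None, None]

        J = np.einsum("ni,nijq,nj->nq", self.xh, dE_hat[self.point_pair], self.xh)
        return r, J


def refine_registration(
    obs: ObservationSet,
    T_init: RigidTransform,
    mode: str = "rigid",
    max_iterations: int = 200,
    cost_tol: float = 1e-10,
    step_tol: float = 1e-12,
) -> RegistrationResult:
    """Minimise the summed squared conic residual over the 6- or 7-DOF pose.

    The rotation is parameterised by a local axis-angle increment composed
    onto the current estimate (singularity-free); ``similarity`` mode adds a
    log-scale parameter. Classic Levenberg–Marquardt with multiplicative
    damping; a step is accepted only if it lowers the cost, so the final cost
    never exceeds the initial one. Convergence: relative cost change below
    ``cost_tol`` or step norm below ``step_tol``.
    """
    if mode not in ("rigid", "similarity"):
        raise SphereregError(f"mode must be 'rigid' or 'similarity', got {mode!r}")
    objective = _Objective(obs, mode)
    R = T_init.rotation.copy()
    t = T_init.translation.copy()
    # rigid mode pins the scale at 1 even if the init carries one (forcing a
    # rigid fit onto non-metric poses is a legitimate diagnostic use)
    s = float(T_init.scale) if mode == "similarity" else 1.0

    r = objective.residuals(R, t, s)
    cost = float(r @ r)
    initial_cost = cost
    lam = 1e-4
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        r, J = objective.residuals_and_jacobian(R, t, s)
        H = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(60):
            A = H + lam * np.diag(np.maximum(np.diag(H), 1e-30))
            try:
                step = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            R_new = R @ Rotation.from_rotvec(step[:3]).as_matrix()
            t_new = t + step[3:6]
            s_new = s * np.exp(step[6]) if mode == "similarity" else 1.0
            r_new = objective.residuals(R_new, t_new, s_new)
            cost_new = float(r_new @ r_new)
            if cost_new <= cost:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            converged = True  # damping exhausted: at a (numerical) minimum
            break
        R, t, s = R_new, t_new, s_new
        lam = max(lam / 3.0, 1e-15)
        rel_drop = (cost - cost_new) / max(cost, 1e-300)
        cost = cost_new
        if rel_drop < cost_tol or np.linalg.norm(step) < step_tol:
            converged = True
            break

    # per-image RMS of the bilinear residual (diagnostic)
    r = objective.residuals(R, t, s)
    per_image = np.zeros(obs.n_images)
    pt_img = objective.img_idx[objective.point_pair]
    for i in range(obs.n_images):
        m = pt_img == i
        per_image[i] = np.sqrt(np.mean(r[m] ** 2)) if m.any() else 0.0

    T = RigidTransform(
        R, t, s if mode == "similarity" else 1.0, T_init.frame_from, T_init.frame_to
    )
    return RegistrationResult(
        transform=T,
        scale=float(s) if mode == "similarity" else 1.0,
        initial_cost=initial_cost,
        final_cost=cost,
        per_image_rms_residual=per_image,
        n_iterations=it,
        converged=converged,
    )


def sphere_center_from_conic(
    conic, cam: Camera, radius: float
) -> np.ndarray:
    """Camera-frame sphere centre implied by a silhouette conic and the radius.

    The pixel conic pulled back to normalised camera coordinates,
    E_n = K^T E K, is proportional to  c c^T - (|c|^2 - r^2) I  with c the
    camera-frame centre: its distinct eigenvalue's eigenvector is the centre
    direction and the eigenvalue ratio fixes the distance, d = r sqrt(1+1/rho)
    with rho = lambda_distinct / (-lambda_pair). If the true marker radius is
    s·radius (a structure-from-motion world of unknown scale s), the returned
    point is the true centre divided by s — its direction is exact and
    inter-point distances match the metric scan, which is what makes
    correspondence search and scale estimation possible without knowing s.
    """
    En = cam.K.T @ conic.matrix @ cam.K
    lam, vec = np.linalg.eigh(En)
    if (lam > 0).sum() == 2:  # fix the overall conic sign: want (+, -, -)
        lam, vec = -lam[::-1], vec[:, ::-1]
    # distinct eigenvalue is the single positive one
    k = int(np.argmax(lam))
    pair = np.delete(lam, k)
    rho = lam[k] / (-pair.mean())
    if rho <= 0 or not np.isfinite(rho):
        raise SphereregError("conic is not a sphere silhouette (bad eigenvalue signs)")
    d = radius * np.sqrt(1.0 + 1.0 / rho)
    v = vec[:, k]
    if v[2] < 0:
        v = -v
    return d * v


def estimate_scale_from_conics(
    detections_per_image: list[list[EllipseDetection]],
    cameras: list[Camera],
    radius: float,
) -> float:
    """Pre-estimate the world scale of SfM camera poses from silhouette sizes.

    For image i, the centroid of the conic-implied camera-frame centres
    (computed with the nominal radius) maps to the world point
    mu_i(s) = s u_i + v_i, where v_i is the camera centre. All images see the
    same physical centroid, so s is the least-squares minimiser of the spread
    of mu_i(s) — a closed form, requiring no correspondences. Assumes every
    contributing image observes the same marker set; images whose detection
    count differs from the mode are skipped.
    """
    counts = [len(d) for d in detections_per_image]
    modal = int(np.bincount([c for c in counts if c > 0]).argmax())
    u, v = [], []
    for dets, cam in zip(detections_per_image, cameras):
        if len(dets) != modal:
            continue
        pts = np.stack(
            [sphere_center_from_conic(d.conic, cam, radius) for d in dets]
        )
        u.append(cam.pose.rotation.T @ pts.mean(axis=0))
        v.append(cam.center_world)
    if len(u) < 2:
        raise SphereregError(
            "scale estimation needs >= 2 images seeing the full marker set"
        )
    u = np.stack(u)
    v = np.stack(v)
    du = u - u.mean(axis=0)
    dv = v - v.mean(axis=0)
    denom = float(np.sum(du * du))
    if denom <= 0:
        raise SphereregError("degenerate camera geometry for scale estimation")
    s = -float(np.sum(du * dv)) / denom
    if s <= 0:
        raise SphereregError(f"scale estimate {s!r} is not positive")
    return s


def register_scene(
    mesh_markers: list[SphereMarker],
    detections_per_image: list[list[EllipseDetection]],
    cameras: list[Camera],
    mode: str = "rigid",
    gate_px: float | None = None,
    init_image: int | None = None,
    outline_source: str = "edge",
) -> tuple[RegistrationResult, dict]:
    """Full pipeline: PnP init -> detection/marker matching -> LM refinement.

    ``detections_per_image`` is aligned with ``cameras``. The initial pose is
    computed on the image with the most detections unless ``init_image`` names
    one. In ``similarity`` mode (SfM poses of unknown scale) the scale is
    pre-estimated from the silhouette sizes so the metric PnP initialisation
    applies to the scaled marker set; in ``rigid`` mode the same fallback is
    tried if plain PnP initialisation fails. Returns the result plus a
    diagnostics dict (init transform, matching/conflict log, per-image
    residual outliers).
    """
    from .detect import match_detections_across_images

    if len(detections_per_image) != len(cameras):
        raise SphereregError("one detection list per camera is required")
    counts = [len(d) for d in detections_per_image]
    if init_image is None:
        init_image = int(np.argmax(counts))
    dets = detections_per_image[init_image]
    if len(dets) < 4:
        raise SphereregError(
            f"stage init: image {init_image} has {len(dets)} detections; need >= 4"
        )
    radius = mesh_markers[0].radius
    centers = np.array([d.center for d in dets])

    def scaled_pnp_init() -> RigidTransform:
        s0 = estimate_scale_from_conics(detections_per_image, cameras, radius)
        scaled = [
            SphereMarker(s0 * m.center, s0 * m.radius, m.frame, m.label)
            for m in mesh_markers
        ]
        T = init_registration_pnp(centers, cameras[init_image], scaled, gate_px)
        # c_W = R (s0 c_S) + t  ==  similarity with rotation R, scale s0
        return RigidTransform(
            T.rotation, T.translation, s0, T.frame_from, T.frame_to
        )

    scale_pre_estimated = False
    try:
        if mode == "similarity":
            T0 = scaled_pnp_init()
            scale_pre_estimated = True
        else:
            try:
                T0 = init_registration_pnp(
                    centers, cameras[init_image], mesh_markers, gate_px
                )
            except InitializationError:
                logger.warning(
                    "plain PnP init failed; retrying with conic-based scale "
                    "pre-estimate (input poses may be non-metric)"
                )
                T0 = scaled_pnp_init()
                scale_pre_estimated = True
    except SphereregError as exc:
        raise type(exc)(f"stage init: {exc}") from exc

    obs, match_log = match_detections_across_images(
        detections_per_image, cameras, mesh_markers, T0,
        gate_px=gate_px, outline_source=outline_source,
    )
    # A PnP init on non-metric poses can be image-consistent in the init view
    # alone (single-view similarity ambiguity) yet project wrongly everywhere
    # else. If matching collapses onto few images, redo the init with the
    # conic-based scale pre-estimate.
    n_expected = sum(min(len(d), len(mesh_markers)) for d in detections_per_image)
    covered_images = len({i for (i, _) in obs.entries})
    if not scale_pre_estimated and (
        covered_images < min(2, len(cameras)) or len(obs.entries) < 0.5 * n_expected
    ):
        logger.warning(
            "matching covered %d/%d expected pairs; re-initialising with "
            "conic-based scale pre-estimate", len(obs.entries), n_expected,
        )
        try:
            T0 = scaled_pnp_init()
            scale_pre_estimated = True
        except SphereregError as exc:
            raise type(exc)(f"stage init: {exc}") from exc
        obs, match_log = match_detections_across_images(
            detections_per_image, cameras, mesh_markers, T0,
            gate_px=gate_px, outline_source=outline_source,
        )
    try:
        result = refine_registration(obs, T0, mode=mode)
    except SphereregError as exc:
        raise type(exc)(f"stage refine: {exc}") from exc
    rms = result.per_image_rms_residual
    flagged = np.flatnonzero(rms > 10.0 * max(np.median(rms), 1e-300))
    diagnostics = {
        "init_image": init_image,
        "init_transform": T0,
        "scale_pre_estimated": scale_pre_estimated,
        "match_log": match_log,
        "n_observations": obs.n_points,
        "high_residual_images": [int(i) for i in flagged],
        # normalised bilinear residuals are ~1e-12 at convergence on clean
        # data and stay below ~1e-5 under pixel noise; a mean far above that
        # signals a model mismatch (e.g. rigid mode on non-metric poses)
        "model_mismatch": bool(np.mean(rms) > 1e-4),
    }
    return result, diagnostics
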