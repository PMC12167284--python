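"""Localising spherical fiducials in a scanned surface mesh.

The markers' radius is known by construction (3D-printed spheres), so the fit
estimates only the centre: starting from a user-supplied approximate centre,
it alternates (ICP-style) between selecting the mesh vertices whose spherical
distance residual lies within a band around zero and a damped Gauss–Newton
update of the centre that minimises sum((||v - c|| - r)^2). A single pass of
3·MAD trimming per iteration discards fringe vertices at the sphere-mount
junction. Only mesh vertices are used, never face interiors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientSupportError, SphereregError
from .geometry import SphereMarker

#: vertices below this count cannot constrain a 3-DOF centre reliably
MIN_SUPPORT = 10

#: default selection band: 10% of the standard 15 mm marker radius
DEFAULT_BAND_MM = 1.5


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface: vertices in millimetres, faces as index triples."""

    vertices: np.ndarray
    faces: np.ndarray
    frame: str = "S"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(v)):
            raise SphereregError("mesh vertices contain NaN/inf")
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise SphereregError("mesh face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass(frozen=True)
class SphereFitResult:
    marker: SphereMarker | None
    rms_residual_mm: float
    n_support_vertices: int
    converged: bool
    n_iterations: int = 0
    rms_history: tuple = ()
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return self.marker is not None and self.converged


def fit_sphere(
    mesh: SurfaceMesh | np.ndarray,
    radius: float,
    init_center: np.ndarray,
    band_mm: float = DEFAULT_BAND_MM,
    max_iterations: int = 100,
    tol_mm: float = 1e-6,
    label: str = "",
) -> SphereFitResult:
    """Fixed-radius sphere fit to mesh vertices from an approximate centre.

    Parameters
    ----------
    mesh : SurfaceMesh or (n, 3) array
        Scan vertices in millimetres; faces are ignored.
    radius : float
        Known marker radius in millimetres (fixed, never estimated).
    init_center : (3,) array
        Approximate centre; must lie within the convergence basin
        (roughly 2·radius of the marker surface).
    band_mm : float
        Half-width of the support band: vertices with
        ``| ||v - c|| - radius | <= band_mm`` participate in the update.

    Raises
    ------
    InsufficientSupportError
        If fewer than :data:`MIN_SUPPORT` vertices fall in the band.
    """
    if band_mm <= 0:
        raise SphereregError(f"band_mm must be positive, got {band_mm}")
    if radius <= 0:
        raise SphereregError(f"radius must be positive, got {radius}")
    verts = mesh.vertices if isinstance(mesh, SurfaceMesh) else np.asarray(mesh, float)
    frame = mesh.frame if isinstance(mesh, SurfaceMesh) else "S"
    c = np.asarray(init_center, dtype=float).reshape(3).copy()

    rms_history: list[float] = []
    converged = False
    n_support = 0
    rms = np.inf
    it = 0
    for it in range(1, max_iterations + 1):
        diff = verts - c
        dist = np.linalg.norm(diff, axis=1)
        rho = dist - radius
        support = np.abs(rho) <= band_mm
        n_support = int(support.sum())
        if n_support < MIN_SUPPORT:
            raise InsufficientSupportError(
                f"insufficient support: {n_support} vertices within "
                f"{band_mm} mm band around radius {radius} mm at centre {c.round(2)}"
            )
        rho_s = rho[support]
        # one MAD-trimming pass: drops mount-junction fringe vertices
        med = np.median(rho_s)
        mad = 1.4826 * np.median(np.abs(rho_s - med))
        if mad > 0:
            keep = np.abs(rho_s - med) <= 3.0 * mad
            if keep.sum() >= MIN_SUPPORT:
                idx = np.flatnonzero(support)[keep]
                support = np.zeros(len(verts), bool)
                support[idx] = True
                rho_s = rho[support]
                n_support = int(support.sum())

        u = (verts[support] - c) / dist[support][:, None]  # unit radial directions
        rms = float(np.sqrt(np.mean(rho_s**2)))

        # Gauss-Newton step for rho_i = ||v_i - c|| - r, d rho/d c = -u_i
        H = u.T @ u
        g = u.T @ rho_s
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]

        # damp the step until the residual on the current support decreases
        alpha = 1.0
        for _ in range(20):
            c_trial = c + alpha * step
            rho_trial = np.linalg.norm(verts[support] - c_trial, axis=1) - radius
            rms_trial = float(np.sqrt(np.mean(rho_trial**2)))
            if rms_trial <= rms * (1 + 1e-15):
                break
            alpha *= 0.5
        rms_history.append(min(rms, rms_trial))
        c = c_trial
        if np.linalg.norm(alpha * step) < tol_mm:
            converged = True
            break

    marker = SphereMarker(c, radius, frame=frame, label=label)
    final_rho = np.linalg.norm(verts - c, axis=1) - radius
    final_support = np.abs(final_rho) <= band_mm
    rms = float(np.sqrt(np.mean(final_rho[final_support] ** 2)))
    return SphereFitResult(
        marker=marker,
        rms_residual_mm=rms,
        n_support_vertices=int(final_support.sum()),
        converged=converged,
        n_iterations=it,
        rms_history=tuple(rms_history),
    )


def localize_markers(
    mesh: SurfaceMesh | np.ndarray,
    radius: float,
    init_centers: np.ndarray,
    band_mm: float = DEFAULT_BAND_MM,
    labels: list[str] | None = None,
) -> list[SphereFitResult]:
    """Fit one sphere per approximate centre; failures are flagged, not fatal.

    ``init_centers`` must be pairwise separated by more than 2·radius so two
    initialisations cannot converge onto the same physical marker.
    Results are ordered as the initialisations; a failed fit yields a result
    with ``marker=None`` and the failure message.
    """
    inits = np.asarray(init_centers, dtype=float).reshape(-1, 3)
    if len(inits) == 0:
        return []
    if labels is None:
        labels = [f"m{k}" for k in range(len(inits))]
    d = np.linalg.norm(inits[:, None, :] - inits[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 2 * radius:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise SphereregError(
            f"initial centres {i} and {j} are {d[i, j]:.2f} mm apart, "
            f"<= 2*radius = {2 * radius:.2f} mm: likely the same marker"
        )
    results = []
    for k, c0 in enumerate(inits):
        try:
            results.append(fit_sphere(mesh, radius, c0, band_mm, label=labels[k]))
        except InsufficientSupportError as exc:
            results.append(
                SphereFitResult(None, np.nan, 0, False, failure=str(exc))
            )
    return results
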