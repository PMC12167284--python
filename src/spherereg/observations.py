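"""Containers linking detected image ellipses to cameras and 3D markers.

An :class:`ObservationSet` indexes outline points x_{ijl} by (image i,
marker j, point l) and carries the per-image cameras and the per-marker
spheres expressed in the scan frame S. It is the single input of the
registration refinement: the objective sums the bilinear conic residual
x^T E_ij x over all stored points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import SphereregError
from .geometry import Camera, Conic, SphereMarker

#: an ellipse has 5 degrees of freedom; fewer points cannot constrain one
MIN_POINTS_PER_PAIR = 5


@dataclass(frozen=True)
class EllipseDetection:
    """One detected marker silhouette in one image.

    ``outline_points`` always lie on the fitted conic (parametric samples);
    ``edge_points``, when present, are the raw sub-pixel boundary points the
    conic was fitted to and may deviate from it by the detection noise.
    """

    conic: Conic
    outline_points: np.ndarray
    support_pixel_count: int
    image_id: str
    edge_points: np.ndarray | None = None
    marker_label: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.outline_points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "outline_points", pts)
        if self.edge_points is not None:
            ep = np.asarray(self.edge_points, dtype=float).reshape(-1, 2)
            object.__setattr__(self, "edge_points", ep)

    @property
    def center(self) -> np.ndarray:
        return self.conic.params()[0]


class ObservationSet:
    """Sparse (image, marker) -> outline-point table feeding the registration.

    Parameters
    ----------
    cameras : list of Camera
        One per image i, poses in the world frame W.
    markers : list of SphereMarker
        One per marker j, centres in the scan frame S.
    entries : dict[(int, int), (L_ij, 2) array]
        Outline points in pixels for each observed (image, marker) pair.
        Pairs may be missing (sparse sum); present pairs need >= 5 points.
    """

    def __init__(
        self,
        cameras: list[Camera],
        markers: list[SphereMarker],
        entries: dict[tuple[int, int], np.ndarray],
    ):
        if len(cameras) < 1:
            raise SphereregError("observation set needs at least one image")
        self.cameras = list(cameras)
        self.markers = list(markers)
        self.entries: dict[tuple[int, int], np.ndarray] = {}
        observed_markers = set()
        for (i, j), pts in entries.items():
            if not (0 <= i < len(cameras)) or not (0 <= j < len(markers)):
                raise SphereregError(f"entry index ({i}, {j}) out of range")
            p = np.asarray(pts, dtype=float).reshape(-1, 2)
            if len(p) < MIN_POINTS_PER_PAIR:
                raise SphereregError(
                    f"entry ({i}, {j}) has {len(p)} outline points; "
                    f"need >= {MIN_POINTS_PER_PAIR}"
                )
            self.entries[(i, j)] = p
            observed_markers.add(j)
        if len(observed_markers) < 3:
            raise SphereregError(
                f"only {len(observed_markers)} distinct markers observed; "
                "registration needs at least 3"
            )

    # -- counts ------------------------------------------------------------

    @property
    def n_images(self) -> int:
        return len(self.cameras)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_points(self) -> int:
        return sum(len(p) for p in self.entries.values())

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to (pair_image_idx, pair_marker_idx, point_pair_idx, points).

        Returns per-pair image/marker index arrays plus, for every stored
        point, the index of its pair and its pixel coordinates — the layout
        the vectorised residual/Jacobian evaluation consumes.
        """
        keys = sorted(self.entries)
        img_idx = np.array([k[0] for k in keys], dtype=np.int64)
        mrk_idx = np.array([k[1] for k in keys], dtype=np.int64)
        counts = np.array([len(self.entries[k]) for k in keys], dtype=np.int64)
        point_pair = np.repeat(np.arange(len(keys)), counts)
        points = np.concatenate([self.entries[k] for k in keys], axis=0)
        return img_idx, mrk_idx, point_pair, points

    def subset_markers(self, marker_indices: list[int]) -> "ObservationSet":
        """Restrict to the given markers (e.g. control markers for evaluation)."""
        remap = {j: k for k, j in enumerate(marker_indices)}
        entries = {
            (i, remap[j]): p for (i, j), p in self.entries.items() if j in remap
        }
        return ObservationSet(
            self.cameras, [self.markers[j] for j in marker_indices], entries
        )
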