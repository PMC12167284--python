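"""Radial error, ellipse reprojection error, and Chamfer distance."""

import numpy as np
import numpy.testing as npt
import pytest
import trimesh
from scipy.spatial import cKDTree

from spherereg import (
    Camera,
    Conic,
    RigidTransform,
    SphereMarker,
    SurfaceMesh,
    chamfer_distance,
    evaluate_registration,
    point_ellipse_distance,
    radial_error,
    reprojection_error,
)
from spherereg.metrics import point_mesh_distance
from spherereg.register import RegistrationResult
from spherereg.transforms import random_rigid_transform

from conftest import look_at


def frontal_camera():
    pose = RigidTransform(np.eye(3), np.zeros(3), 1.0, "W", "C")
    return Camera(1000.0, 1000.0, 500.0, 500.0, 1000, 1000, pose)


class TestRadialError:
    def test_center_ray_returns_radius(self):
        cam = frontal_camera()
        m = SphereMarker([0, 0, 1000.0], 15.0, "W")
        npt.assert_allclose(radial_error([[500.0, 500.0]], cam, m), [15.0])

    def test_tangent_ray_returns_zero(self):
        cam = frontal_camera()
        m = SphereMarker([0, 0, 1000.0], 15.0, "W")
        px = 500.0 + 1000.0 * np.tan(np.arcsin(15.0 / 1000.0))
        npt.assert_allclose(radial_error([[px, 500.0]], cam, m), [0.0], atol=1e-12)

    def test_offset_ray_arithmetic(self):
        # a ray at perpendicular distance 16 mm from an r=15 sphere -> 1 mm
        cam = frontal_camera()
        m = SphereMarker([16.0, 0.0, 1000.0], 15.0, "W")
        # ray through the principal point passes at distance 16*cos(theta)...
        # instead aim the ray parallel to z through x=0: pixel (500,500)
        d = radial_error([[500.0, 500.0]], cam, m)[0]
        perp = np.linalg.norm(np.cross(m.center, [0, 0, 1.0]))
        npt.assert_allclose(d, abs(perp - 15.0), atol=1e-12)

    def test_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(8)
        cam = frontal_camera()
        m = SphereMarker([30.0, -20.0, 900.0], 15.0, "W")
        pts = rng.uniform(400, 600, size=(20, 2))
        e1 = radial_error(pts, cam, m)
        G = random_rigid_transform(rng, "W", "W2", translation_scale=500.0)
        cam2 = Camera(cam.fx, cam.fy, cam.cx, cam.cy, cam.width, cam.height,
                      cam.pose @ G.inverse())
        e2 = radial_error(pts, cam2, m.transformed(G))
        npt.assert_allclose(e1, e2, atol=1e-10)

    def test_marker_behind_camera_rejected(self):
        cam = frontal_camera()
        m = SphereMarker([0, 0, -1000.0], 15.0, "W")
        with pytest.raises(Exception, match="behind"):
            radial_error([[500.0, 500.0]], cam, m)


class TestReprojectionError:
    def test_identical_ellipses_zero(self):
        E = Conic.from_params([10.0, 20.0], [40.0, 25.0], 0.5)
        assert reprojection_error(E, E) < 1e-12

    def test_concentric_circles_exact_gap(self):
        a = Conic.from_params([0.0, 0.0], [100.0, 100.0], 0.0)
        b = Conic.from_params([0.0, 0.0], [103.0, 103.0], 0.0)
        npt.assert_allclose(reprojection_error(a, b), 3.0, atol=1e-9)

    def test_translated_congruent_ellipses_match_dense_oracle(self):
        shift = 4.0
        e1 = Conic.from_params([50.0, -20.0], [30.0, 10.0], 0.3)
        e2 = Conic.from_params([50.0 + shift, -20.0], [30.0, 10.0], 0.3)
        v = reprojection_error(e1, e2, n_samples=200)
        assert 0.0 < v < shift
        # dense-sampling oracle
        dense1 = e1.sample_outline(100_000)
        dense2 = e2.sample_outline(100_000)
        o = 0.5 * (
            cKDTree(dense2).query(e1.sample_outline(200))[0].mean()
            + cKDTree(dense1).query(e2.sample_outline(200))[0].mean()
        )
        npt.assert_allclose(v, o, rtol=1e-3)

    def test_shifted_circles_match_small_shift_closed_form(self):
        # circles of radius R shifted by delta << R: the foot-point distance
        # from a point at polar angle theta is ~ delta |cos theta|, whose mean
        # over the circle is 2 delta / pi
        shift = 4.0
        e1 = Conic.from_params([0.0, 0.0], [30.0, 30.0], 0.0)
        e2 = Conic.from_params([shift, 0.0], [30.0, 30.0], 0.0)
        v = reprojection_error(e1, e2, 2000)
        assert 0.0 < v < shift
        npt.assert_allclose(v, 2 * shift / np.pi, rtol=0.02)

    def test_convergence_in_sample_count(self):
        e1 = Conic.from_params([0.0, 0.0], [50.0, 20.0], 0.2)
        e2 = Conic.from_params([3.0, -2.0], [48.0, 22.0], 0.3)
        v1 = reprojection_error(e1, e2, 400)
        v2 = reprojection_error(e1, e2, 800)
        assert abs(v2 - v1) / v1 < 0.01

    def test_foot_point_distance_matches_brute_force(self):
        E = Conic.from_params([50.0, -20.0], [30.0, 10.0], 0.3)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-60, 120, size=(100, 2))
        d = point_ellipse_distance(E, pts)
        brute = cKDTree(E.sample_outline(200_000)).query(pts)[0]
        npt.assert_allclose(d, brute, atol=1e-5)

    def test_degenerate_conic_rejected(self):
        H = Conic(np.diag([1.0, -1.0, -1.0]))
        E = Conic.from_params([0.0, 0.0], [10.0, 5.0], 0.0)
        with pytest.raises(Exception, match="ellipse"):
            reprojection_error(E, H)


def icosphere_mesh(radius, subdivisions=5, center=(0, 0, 0)):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(m.vertices) + center, np.asarray(m.faces), "S")


class TestChamfer:
    def test_self_distance_zero(self):
        a = icosphere_mesh(15.0, subdivisions=3)
        assert chamfer_distance(a, a, n_samples=3000) < 1e-12

    def test_concentric_spheres_gap(self):
        a = icosphere_mesh(15.0)
        b = icosphere_mesh(16.0)
        # polyhedral surfaces: exact up to the facet sag (~2e-3 mm at subdiv 5)
        npt.assert_allclose(chamfer_distance(a, b, n_samples=20000), 1.0, atol=1e-2)

    def test_symmetry(self):
        a = icosphere_mesh(15.0, subdivisions=3)
        b = icosphere_mesh(17.0, subdivisions=3, center=(1.0, 0, 0))
        d1 = chamfer_distance(a, b, n_samples=5000, seed=3)
        d2 = chamfer_distance(b, a, n_samples=5000, seed=3)
        npt.assert_allclose(d1, d2, rtol=1e-12)

    def test_small_translation_bounds_distance(self):
        delta = 0.05  # small vs facet size
        a = icosphere_mesh(15.0, subdivisions=4)
        b = SurfaceMesh(a.vertices + [delta, 0.0, 0.0], a.faces, "S")
        d = chamfer_distance(a, b, n_samples=20000)
        assert 0.0 < d <= delta

    def test_point_mesh_distance_exact_on_vertices(self):
        a = icosphere_mesh(15.0, subdivisions=3)
        d = point_mesh_distance(a.vertices[:50], a)
        npt.assert_allclose(d, 0.0, atol=1e-12)

    def test_empty_mesh_rejected(self):
        a = icosphere_mesh(15.0, subdivisions=2)
        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int), "S")
        with pytest.raises(Exception, match="non-empty"):
            chamfer_distance(a, empty)

    def test_statistic_variants(self):
        a = icosphere_mesh(15.0, subdivisions=3)
        b = icosphere_mesh(16.0, subdivisions=3)
        mean = chamfer_distance(a, b, n_samples=4000, statistic="mean")
        rms = chamfer_distance(a, b, n_samples=4000, statistic="rms")
        med = chamfer_distance(a, b, n_samples=4000, statistic="median")
        assert rms >= mean > 0 and med > 0


class TestEvaluateRegistration:
    def test_noise_free_pipeline_error_vanishes(self, small_scene):
        truth = RegistrationResult(
            transform=small_scene.true_transform, scale=1.0,
            initial_cost=1.0, final_cost=0.0,
            per_image_rms_residual=np.zeros(len(small_scene.cameras)),
            n_iterations=0, converged=True,
        )
        rep = evaluate_registration(truth, small_scene.exact_control_observations)
        assert rep.mean_mm < 1e-8

    def test_report_mean_equals_mean_of_points(self, small_scene):
        truth = RegistrationResult(
            transform=small_scene.true_transform, scale=1.0,
            initial_cost=1.0, final_cost=0.0,
            per_image_rms_residual=np.zeros(len(small_scene.cameras)),
            n_iterations=0, converged=True,
        )
        rep = evaluate_registration(truth, small_scene.exact_control_observations)
        npt.assert_allclose(rep.mean_mm, rep.errors_mm.mean())
        # overall mean is the count-weighted mean of per-marker means
        per = rep.per_marker_mean()
        weights = [np.sum(rep.point_marker == j) for j in per]
        npt.assert_allclose(
            rep.mean_mm,
            np.average([per[j] for j in per], weights=weights),
        )

    def test_translation_toward_marker_maps_to_radial_error(self):
        # single fronto-parallel camera, control marker on the optical axis:
        # translating the registration along the axis leaves the tangency
        # deficit of on-outline rays between 0 and the translation magnitude
        cam = frontal_camera()
        from spherereg import ObservationSet, project_sphere

        centers = np.array(
            [[0.0, 0.0, 1000.0], [80.0, 0.0, 1000.0], [-80.0, 0.0, 1000.0]]
        )
        markers_S = [SphereMarker(c, 15.0, "S") for c in centers]
        entries = {
            (0, j): project_sphere(SphereMarker(c, 15.0, "W"), cam).sample_outline(40)
            for j, c in enumerate(centers)
        }
        obs = ObservationSet([cam], markers_S, entries)
        shifted = RegistrationResult(
            transform=RigidTransform(np.eye(3), [0, 0, 1.0], 1.0, "S", "W"),
            scale=1.0, initial_cost=1.0, final_cost=0.0,
            per_image_rms_residual=np.zeros(1), n_iterations=0, converged=True,
        )
        rep = evaluate_registration(shifted, obs)
        assert 0.0 < rep.mean_mm < 1.0
        # oracle: exact per-ray geometry against the shifted centres
        for j, c in enumerate(centers):
            origin, dirs = cam.back_project_rays(obs.entries[(0, j)])
            oc = c + [0.0, 0.0, 1.0] - origin
            perp = np.linalg.norm(oc[None, :] - (dirs @ oc)[:, None] * dirs, axis=1)
            npt.assert_allclose(
                rep.errors_mm[rep.point_marker == j], np.abs(perp - 15.0),
                atol=1e-12,
            )

    def test_empty_control_set_rejected(self, small_scene):
        truth = RegistrationResult(
            transform=small_scene.true_transform, scale=1.0,
            initial_cost=1.0, final_cost=0.0,
            per_image_rms_residual=np.zeros(1), n_iterations=0, converged=True,
        )
        obs = small_scene.exact_control_observations
        obs2 = object.__new__(type(obs))
        obs2.cameras = obs.cameras
        obs2.markers = obs.markers
        obs2.entries = {}
        with pytest.raises(Exception, match="empty"):
            evaluate_registration(truth, obs2)
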