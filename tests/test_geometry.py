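"""Sphere quadrics, conic projection against the tangent-cone oracle, and
conic parameter conversions."""

import numpy as np
import numpy.testing as npt
import pytest

from spherereg import (
    Camera,
    Conic,
    DegenerateConicError,
    DegenerateSilhouetteError,
    RigidTransform,
    SphereMarker,
    conic_to_params,
    project_sphere,
    sample_outline,
    sphere_dual_quadric,
    sphere_quadric,
)
from spherereg.transforms import random_rigid_transform

from conftest import look_at, make_camera, random_visible_pair, silhouette_pixels


class TestSphereQuadric:
    def test_unit_sphere_is_canonical_diagonal(self):
        Q = sphere_quadric(SphereMarker([0, 0, 0], 1.0, "W"))
        npt.assert_allclose(Q, np.diag([1.0, 1.0, 1.0, -1.0]))

    def test_surface_point_annihilates_quadric(self):
        Q = sphere_quadric(SphereMarker([0, 0, 0], 15.0, "W"))
        x = np.array([15.0, 0.0, 0.0, 1.0])
        assert abs(x @ Q @ x) < 1e-12

    def test_quadric_matches_expanded_distance_form(self):
        # oracle: ||x-c||^2 - r^2 expanded as a quadratic form, checked at
        # 100 random surface points
        c = np.array([10.0, 20.0, 30.0])
        r = 15.0
        Q = sphere_quadric(SphereMarker(c, r, "W"))
        npt.assert_allclose(Q, Q.T)
        rng = np.random.default_rng(0)
        v = rng.normal(size=(100, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = c + r * v
        ph = np.concatenate([pts, np.ones((100, 1))], axis=1)
        npt.assert_allclose(np.einsum("ni,ij,nj->n", ph, Q, ph), 0.0, atol=1e-10)
        # and off-surface points give the squared distance defect
        pts2 = c + 2 * r * v
        ph2 = np.concatenate([pts2, np.ones((100, 1))], axis=1)
        npt.assert_allclose(
            np.einsum("ni,ij,nj->n", ph2, Q, ph2), (2 * r) ** 2 - r**2, atol=1e-9
        )

    def test_dual_quadric_is_scaled_adjugate(self):
        m = SphereMarker([3.0, -2.0, 7.0], 4.0, "W")
        Q = sphere_quadric(m)
        Qd = sphere_dual_quadric(m)
        prod = Q @ Qd
        npt.assert_allclose(prod, prod[0, 0] * np.eye(4), atol=1e-9)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(Exception, match="radius"):
            SphereMarker([0, 0, 0], -1.0, "W")


class TestProjection:
    def test_on_axis_sphere_projects_to_circle_of_known_radius(self):
        pose = RigidTransform(np.eye(3), np.zeros(3), 1.0, "W", "C")
        cam = Camera(1000, 1000, 0.0, 0.0, 1000, 1000, pose)
        m = SphereMarker([0, 0, 1000.0], 100.0, "W")
        center, axes, _ = project_sphere(m, cam).params()
        expected = 1000 * 100 / np.sqrt(1000**2 - 100**2)  # f r / sqrt(d^2-r^2)
        npt.assert_allclose(center, [0.0, 0.0], atol=1e-9)
        npt.assert_allclose(axes, expected, rtol=1e-12)

    def test_outline_points_satisfy_bilinear_identity(self):
        m, cam = random_visible_pair(np.random.default_rng(1))
        E = project_sphere(m, cam)
        pts = sample_outline(E, 50)
        assert np.abs(E.evaluate(pts)).max() < 1e-9

    def test_eccentricity_grows_off_axis(self):
        pose = RigidTransform(np.eye(3), np.zeros(3), 1.0, "W", "C")
        cam = Camera(1000, 1000, 2000.0, 2000.0, 4000, 4000, pose)
        ecc = []
        for x in [0.0, 150.0, 300.0, 450.0, 600.0]:
            _, (a, b), _ = project_sphere(
                SphereMarker([x, 0, 1000.0], 100.0, "W"), cam
            ).params()
            assert a >= b
            ecc.append(a / b)
        assert np.all(np.diff(ecc) > 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_analytic_conic_agrees_with_tangent_cone_oracle(self, seed):
        m, cam = random_visible_pair(np.random.default_rng(seed))
        E = project_sphere(m, cam)
        px = silhouette_pixels(m, cam, n=2000)
        assert np.abs(E.evaluate(px)).max() < 1e-6

    def test_projection_equivariant_under_world_change(self):
        rng = np.random.default_rng(5)
        m, cam = random_visible_pair(rng)
        G = random_rigid_transform(rng, "W", "W2", translation_scale=200.0)
        m2 = m.transformed(G)
        cam2 = Camera(
            cam.fx, cam.fy, cam.cx, cam.cy, cam.width, cam.height,
            cam.pose @ G.inverse(),
        )
        E1 = project_sphere(m, cam)
        E2 = project_sphere(m2, cam2)
        npt.assert_allclose(E1.matrix, E2.matrix, atol=1e-9)

    def test_sphere_behind_camera_is_degenerate(self):
        pose = RigidTransform(np.eye(3), np.zeros(3), 1.0, "W", "C")
        cam = Camera(1000, 1000, 500.0, 500.0, 1000, 1000, pose)
        with pytest.raises(DegenerateSilhouetteError, match="degenerate silhouette"):
            project_sphere(SphereMarker([0, 0, -500.0], 50.0, "W"), cam)
        with pytest.raises(DegenerateSilhouetteError, match="degenerate silhouette"):
            project_sphere(SphereMarker([0, 0, 10.0], 50.0, "W"), cam)


class TestConicParams:
    def test_canonical_circle(self):
        E = Conic(np.diag([1.0, 1.0, -100.0]))
        center, axes, angle = conic_to_params(E)
        npt.assert_allclose(center, [0.0, 0.0], atol=1e-12)
        npt.assert_allclose(axes, [10.0, 10.0], rtol=1e-12)
        assert angle == 0.0

    def test_params_round_trip_preserves_matrix(self):
        E = Conic.from_params([50.0, -20.0], [30.0, 10.0], 0.3)
        center, axes, angle = E.params()
        npt.assert_allclose(center, [50.0, -20.0], rtol=1e-9)
        npt.assert_allclose(axes, [30.0, 10.0], rtol=1e-9)
        npt.assert_allclose(angle, 0.3, rtol=1e-9)
        E2 = Conic.from_params(center, axes, angle)
        npt.assert_allclose(E2.matrix, E.matrix, atol=1e-9)

    def test_constructed_ellipse_contains_its_parametric_points(self):
        E = Conic.from_params([50.0, -20.0], [30.0, 10.0], 0.3)
        t = np.linspace(0, 2 * np.pi, 100)
        u = np.array([np.cos(0.3), np.sin(0.3)])
        v = np.array([-np.sin(0.3), np.cos(0.3)])
        pts = [50.0, -20.0] + np.outer(30 * np.cos(t), u) + np.outer(10 * np.sin(t), v)
        assert np.abs(E.evaluate(pts)).max() < 1e-12

    def test_hyperbola_rejected(self):
        H = Conic(np.diag([1.0, -1.0, -1.0]))  # x^2 - y^2 = 1
        assert not H.is_ellipse
        with pytest.raises(DegenerateConicError):
            H.params()

    def test_normalisation_convention(self):
        E = Conic.from_params([5.0, 5.0], [4.0, 2.0], 1.0)
        assert np.isclose(np.linalg.norm(E.matrix), 1.0)
        assert np.trace(E.matrix[:2, :2]) > 0
        npt.assert_allclose(E.matrix, E.matrix.T, atol=1e-15)
        # scale invariance of the representation
        E2 = Conic(-37.5 * E.matrix)
        npt.assert_allclose(E2.matrix, E.matrix, atol=1e-12)


class TestOutlineSampling:
    def test_unit_circle_cardinal_points(self):
        E = Conic(np.diag([1.0, 1.0, -1.0]))
        pts = sample_outline(E, 4)
        npt.assert_allclose(
            pts, [[1, 0], [0, 1], [-1, 0], [0, -1]], atol=1e-12
        )

    def test_uniform_parametric_spacing(self):
        E = Conic.from_params([12.0, 8.0], [25.0, 11.0], -0.7)
        pts = sample_outline(E, 20)
        center, (a, b), phi = E.params()
        q = pts - center
        ca, sa = np.cos(phi), np.sin(phi)
        x = (q[:, 0] * ca + q[:, 1] * sa) / a
        y = (-q[:, 0] * sa + q[:, 1] * ca) / b
        th = np.unwrap(np.arctan2(y, x))
        npt.assert_allclose(np.diff(th), 2 * np.pi / 20, atol=1e-9)

    def test_too_few_samples_rejected(self):
        E = Conic(np.diag([1.0, 1.0, -1.0]))
        with pytest.raises(Exception, match="4"):
            sample_outline(E, 3)
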