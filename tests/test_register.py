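"""PnP correspondence search, LM conic-residual refinement, full pipeline."""

import numpy as np
import numpy.testing as npt
import pytest
from scipy.spatial.transform import Rotation

from spherereg import (
    Camera,
    InitializationError,
    ObservationSet,
    RigidTransform,
    SceneConfig,
    SphereMarker,
    SphereregError,
    estimate_scale_from_conics,
    generate_scene,
    init_registration_pnp,
    project_sphere,
    refine_registration,
    register_scene,
    sphere_center_from_conic,
)
from spherereg.register import _Objective

from conftest import make_camera


def perturbed(T, rot_rad=0.02, trans_mm=3.0, seed=0):
    rng = np.random.default_rng(seed)
    dR = Rotation.from_rotvec(rng.normal(size=3) * rot_rad / np.sqrt(3)).as_matrix()
    return RigidTransform(
        T.rotation @ dR,
        T.translation + rng.normal(size=3) * trans_mm / np.sqrt(3),
        1.0, T.frame_from, T.frame_to,
    )


class TestPnPInit:
    def test_minimal_exact_case_with_projected_centers(self):
        rng = np.random.default_rng(0)
        cam = make_camera()
        centers_S = rng.uniform(-150, 150, (4, 3))
        centers_S[:, 2] *= 0.2
        T = RigidTransform(
            Rotation.from_rotvec([0.2, -0.1, 0.3]).as_matrix(),
            [20.0, -30.0, 10.0], 1.0, "S", "W",
        )
        markers = [SphereMarker(c, 15.0, "S") for c in centers_S]
        px = cam.project_points(T.apply(centers_S))
        T0 = init_registration_pnp(px, cam, markers)
        # exact up to the P3P quartic-root tolerance
        assert T0.rotation_angle_to(T) < 1e-6
        assert T0.translation_distance_to(T) < 1e-4

    def test_correspondence_found_with_shuffled_detections(self, small_scene):
        scene = small_scene
        cam = scene.cameras[0]
        mk_W = [m.transformed(scene.true_transform) for m in scene.markers]
        centers = np.array(
            [project_sphere(m, cam).params()[0] for m in mk_W]
        )
        rng = np.random.default_rng(1)
        T0 = init_registration_pnp(centers[rng.permutation(10)], cam, scene.markers)
        # ellipse centres carry the perspective bias, so the init is close
        # but not exact — within the documented 2 mm / 0.5 deg envelope
        assert T0.rotation_angle_to(scene.true_transform) < np.deg2rad(0.5)
        assert T0.translation_distance_to(scene.true_transform) < 2.0

    def test_three_detections_rejected(self, small_scene):
        with pytest.raises(SphereregError, match=">= 4"):
            init_registration_pnp(
                np.zeros((3, 2)), small_scene.cameras[0], small_scene.markers
            )

    def test_unmatchable_centers_raise_initialization_error(self, small_scene):
        rng = np.random.default_rng(2)
        bogus = rng.uniform(0, 2000, (6, 2))
        with pytest.raises(InitializationError, match="well visible"):
            init_registration_pnp(bogus, small_scene.cameras[0], small_scene.markers)


class TestRefinement:
    def test_noise_free_recovery_from_perturbed_init(self, small_scene):
        scene = small_scene
        T0 = perturbed(scene.true_transform, np.deg2rad(2.0), 5.0)
        res = refine_registration(scene.exact_observations, T0, "rigid")
        assert res.converged
        assert res.transform.rotation_angle_to(scene.true_transform) < 1e-6
        assert res.transform.translation_distance_to(scene.true_transform) < 1e-6
        assert res.final_cost < 1e-18

    def test_start_at_optimum_terminates_immediately(self, small_scene):
        res = refine_registration(
            small_scene.exact_observations, small_scene.true_transform, "rigid"
        )
        assert res.converged and res.n_iterations <= 2
        assert res.final_cost <= res.initial_cost

    def test_similarity_recovers_true_scale(self):
        scene = generate_scene(
            SceneConfig(seed=5, true_scale=1.5, mesh_subdivisions=1)
        )
        T0 = perturbed(scene.true_transform, np.deg2rad(1.0), 3.0)
        T0 = RigidTransform(T0.rotation, T0.translation, 1.2, "S", "W")
        res = refine_registration(scene.exact_observations, T0, "similarity")
        assert abs(res.scale - 1.5) < 1.5e-6
        assert res.final_cost < 1e-18

    def test_rigid_mode_reports_scale_one(self, small_scene):
        res = refine_registration(
            small_scene.exact_observations, small_scene.true_transform, "rigid"
        )
        assert res.scale == 1.0 and res.transform.scale == 1.0

    def test_final_cost_never_exceeds_initial(self, small_scene):
        T0 = perturbed(small_scene.true_transform, np.deg2rad(3.0), 10.0, seed=5)
        res = refine_registration(small_scene.noisy_observations, T0, "rigid")
        assert res.final_cost <= res.initial_cost

    @pytest.mark.parametrize("mode,npar", [("rigid", 6), ("similarity", 7)])
    def test_analytic_jacobian_matches_finite_differences(
        self, small_scene, mode, npar
    ):
        obs = small_scene.exact_observations
        obj = _Objective(obs, mode)
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(10):  # random states near the truth
            T = perturbed(
                small_scene.true_transform, 0.05, 10.0, seed=rng.integers(1 << 30)
            )
            R0, t0 = T.rotation, T.translation
            s0 = float(rng.uniform(0.8, 1.2)) if mode == "similarity" else 1.0
            _, J = obj.residuals_and_jacobian(R0, t0, s0)
            eps = 1e-6
            Jfd = np.zeros_like(J)
            for k in range(npar):
                d = np.zeros(npar)
                d[k] = eps
                rp = obj.residuals(
                    R0 @ Rotation.from_rotvec(d[:3]).as_matrix(),
                    t0 + d[3:6], s0 * np.exp(d[6]) if npar == 7 else 1.0,
                )
                rm = obj.residuals(
                    R0 @ Rotation.from_rotvec(-d[:3]).as_matrix(),
                    t0 - d[3:6], s0 * np.exp(-d[6]) if npar == 7 else 1.0,
                )
                Jfd[:, k] = (rp - rm) / (2 * eps)
            worst = max(worst, np.abs(J - Jfd).max() / np.abs(Jfd).max())
        assert worst < 1e-6


class TestGaugeConsistency:
    def test_world_frame_change_transports_solution(self, small_scene):
        from spherereg.transforms import random_rigid_transform

        scene = small_scene
        rng = np.random.default_rng(9)
        G = random_rigid_transform(rng, "W", "W2", translation_scale=300.0)
        cams2 = [
            Camera(c.fx, c.fy, c.cx, c.cy, c.width, c.height,
                   c.pose @ G.inverse(), c.camera_id)
            for c in scene.cameras
        ]
        obs2 = ObservationSet(
            cams2, scene.markers,
            {k: v.copy() for k, v in scene.exact_observations.entries.items()},
        )
        T0 = perturbed(scene.true_transform, 0.01, 3.0)
        res1 = refine_registration(scene.exact_observations, T0, "rigid")
        T0g = RigidTransform(
            G.rotation @ T0.rotation, G.apply(T0.translation), 1.0, "S", "W2"
        )
        res2 = refine_registration(obs2, T0g, "rigid")
        expected = G @ res1.transform
        assert res2.transform.rotation_angle_to(expected) < 1e-8
        assert res2.transform.translation_distance_to(expected) < 1e-6


class TestScaleFromConics:
    def test_camera_frame_center_from_conic_is_exact(self, small_scene):
        scene = small_scene
        cam = scene.cameras[3]
        m = scene.markers[2].transformed(scene.true_transform)
        conic = project_sphere(m, cam)
        est = sphere_center_from_conic(conic, cam, m.radius)
        npt.assert_allclose(est, cam.pose.apply(m.center), rtol=1e-9)

    @pytest.mark.parametrize("s_true", [0.5, 1.0, 2.0])
    def test_scale_estimate_without_correspondences(self, s_true):
        scene = generate_scene(
            SceneConfig(seed=8, true_scale=s_true, mesh_subdivisions=1)
        )
        s = estimate_scale_from_conics(
            scene.detections(noisy=False), scene.cameras, 15.0
        )
        npt.assert_allclose(s, s_true, rtol=1e-9)


class TestRegisterScene:
    def test_end_to_end_noise_free(self, small_scene):
        from spherereg import evaluate_registration

        scene = small_scene
        res, diag = register_scene(
            scene.markers, scene.detections(noisy=False), scene.cameras, "rigid"
        )
        rep = evaluate_registration(res, scene.exact_control_observations)
        assert rep.mean_mm < 1e-8
        assert not diag["model_mismatch"]

    def test_submillimeter_under_pixel_noise(self, noisy_scene):
        from spherereg import evaluate_registration

        scene = noisy_scene
        res, _ = register_scene(
            scene.markers, scene.detections(noisy=True), scene.cameras, "rigid"
        )
        rep = evaluate_registration(res, scene.exact_control_observations)
        assert rep.mean_mm < 1.0

    def test_similarity_pipeline_recovers_sfm_scale(self):
        scene = generate_scene(
            SceneConfig(seed=13, true_scale=1.5, mesh_subdivisions=1)
        )
        res, diag = register_scene(
            scene.markers, scene.detections(noisy=False), scene.cameras,
            "similarity",
        )
        assert diag["scale_pre_estimated"]
        assert abs(res.scale - 1.5) / 1.5 < 1e-6

    def test_rigid_mode_on_scaled_input_flags_mismatch(self):
        scene = generate_scene(
            SceneConfig(seed=5, true_scale=1.5, mesh_subdivisions=1)
        )
        res, diag = register_scene(
            scene.markers, scene.detections(noisy=False), scene.cameras, "rigid"
        )
        assert res.converged
        assert res.final_cost > 1e-6  # orders above the noise floor
        assert diag["model_mismatch"]

    def test_mismatched_lengths_rejected(self, small_scene):
        with pytest.raises(SphereregError, match="per camera"):
            register_scene(small_scene.markers, [[]], small_scene.cameras)
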