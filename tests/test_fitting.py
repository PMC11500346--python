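"""Loss terms and the silhouette+anthropometry optimization."""

import numpy as np
import pytest

from meshcomp import autodiff as ad
from meshcomp.bodymodel import PoseShape, forward, forward_tensors, shaped_vertices_t
from meshcomp.fitting import (
    FitConfig,
    InitialEstimate,
    LossWeights,
    SilhouetteFitModel,
    anthropometry_loss,
    fit_mesh,
    scanbed_loss,
    silhouette_loss,
)
from meshcomp.measurements import Anthropometry, mesh_anthropometry
from meshcomp.silhouette import hard_rasterize, project_points
from meshcomp.synthetic import GeneratorConfig, generate_cohort, standard_camera


def _anthro(**kw):
    base = dict(height=1.68, waist_circ=0.71, hip_circ=0.90, weight=70.0, sex="female")
    base.update(kw)
    return Anthropometry(**base)


class TestAnthropometryLoss:
    def test_zero_iff_exact_match(self):
        w = LossWeights()
        t = _anthro()
        measures = {"waist": t.waist_circ, "hip": t.hip_circ, "height": t.height}
        assert float(anthropometry_loss(measures, t, w).item()) == 0.0
        measures["waist"] = t.waist_circ + 1e-3
        assert float(anthropometry_loss(measures, t, w).item()) > 0.0

    def test_single_term_square(self):
        w = LossWeights(l1=1.0, l2=0.0, l3=0.0, l4=1.0)
        t = _anthro()
        measures = {"waist": t.waist_circ + 0.02, "hip": t.hip_circ, "height": t.height}
        assert abs(float(anthropometry_loss(measures, t, w).item()) - 4e-4) < 1e-12

    def test_gradient_through_circumference(self, model, rng):
        from meshcomp.measurements import circumference_t, height_t

        w = LossWeights(l1=1.0, l2=1.0, l3=1.0, l4=0.0)
        t = _anthro()
        beta0 = rng.normal(size=model.n_shape) * 0.3

        def loss_val(b):
            vs = shaped_vertices_t(model, ad.tensor(b))
            measures = {
                "waist": circumference_t(model, vs, "waist"),
                "hip": circumference_t(model, vs, "hip"),
                "height": height_t(model, ad.tensor(b)),
            }
            return anthropometry_loss(measures, t, w)

        bt = ad.tensor(beta0.copy(), requires_grad=True)
        vs = shaped_vertices_t(model, bt)
        from meshcomp.measurements import circumference_t as ct

        measures = {
            "waist": ct(model, vs, "waist"),
            "hip": ct(model, vs, "hip"),
            "height": height_t(model, bt),
        }
        anthropometry_loss(measures, t, w).backward()
        eps = 1e-6
        for i in [0, 1, 2, 3]:
            bp, bm = beta0.copy(), beta0.copy()
            bp[i] += eps
            bm[i] -= eps
            fd = (float(loss_val(bp).item()) - float(loss_val(bm).item())) / (2 * eps)
            assert abs(bt.grad[i] - fd) <= 1e-3 * max(abs(fd), 1e-5)


class TestSilhouetteLoss:
    def test_self_consistency_small(self, model):
        cam = standard_camera()
        mesh = forward(model, PoseShape.zeros(model))
        s_gt = hard_rasterize(mesh, cam)
        j2d = project_points(mesh.joints, cam)
        w = LossWeights(l4=1.0, l5=1.0)
        val = silhouette_loss(mesh, cam, s_gt, j2d, w, sharpness=25.0)
        # pixel term limited by renderer softness at the boundary only
        assert val < 5e-3

    def test_displaced_joints_pythagorean(self, model):
        cam = standard_camera()
        mesh = forward(model, PoseShape.zeros(model))
        s_gt = hard_rasterize(mesh, cam)
        j2d = project_points(mesh.joints, cam) + np.array([3.0, 4.0])
        w = LossWeights(l4=0.0, l5=1.0)
        val = silhouette_loss(mesh, cam, s_gt, j2d, w)
        assert abs(val - 25.0 * model.n_joints) < 1e-9

    def test_loss_decreases_narrowing_too_wide_torso(self, model):
        """1-D scan along the waist-girth direction toward the target."""
        cam = standard_camera()
        target_beta = np.zeros(model.n_shape)
        s_gt = hard_rasterize(forward(model, PoseShape(np.zeros((model.n_joints, 3)), target_beta)), cam)
        w = LossWeights(l4=1.0, l5=0.0)
        vals = []
        for g in [2.0, 1.0, 0.5, 0.0]:
            b = target_beta.copy()
            b[2] = g  # waist girth direction
            mesh = forward(model, PoseShape(np.zeros((model.n_joints, 3)), b))
            j2d = project_points(mesh.joints, cam)
            vals.append(silhouette_loss(mesh, cam, s_gt, j2d, w))
        assert vals[0] > vals[1] > vals[2] > vals[3]


class TestScanbedLoss:
    def test_ideal_supine_pose_is_zero(self, model):
        pose = np.zeros((model.n_joints, 3))
        joints = model.rest_joints
        w = LossWeights()
        assert scanbed_loss(pose, pose, joints, model, w) == pytest.approx(0.0, abs=1e-30)

    def test_single_spine_bend_term(self, model):
        pose = np.zeros((model.n_joints, 3))
        j = model.joint_names.index("spine")
        pose[j, 0] = 0.1
        w = LossWeights(l6=1.0, l7=0.0, l8=0.0)
        val = scanbed_loss(pose, np.zeros_like(pose), model.rest_joints, model, w)
        assert abs(val - 0.01) < 1e-12

    def test_gradient_flattens_forward_leaning_torso(self, model):
        """The loss decreases along the corrective direction of a leaning spine."""
        w = LossWeights(l6=1.0, l7=0.0, l8=0.0)
        pose = np.zeros((model.n_joints, 3))
        j = model.joint_names.index("spine")
        pose[j, 0] = 0.2
        v0 = scanbed_loss(pose, np.zeros_like(pose), model.rest_joints, model, w)
        corrected = pose.copy()
        corrected[j, 0] = 0.1
        assert scanbed_loss(corrected, np.zeros_like(pose), model.rest_joints, model, w) < v0

    def test_arm_depth_term(self, model):
        w = LossWeights(l6=0.0, l7=0.0, l8=1.0)
        joints = model.rest_joints.copy()
        depth_ids = model.joint_groups["arm_joints_depth"]
        joints[depth_ids, 2] += 0.1
        val = scanbed_loss(
            np.zeros((model.n_joints, 3)), np.zeros((model.n_joints, 3)), joints, model, w
        )
        assert abs(val - 0.01 * len(depth_ids)) < 1e-9


class TestFitMesh:
    @pytest.fixture(scope="class")
    def subject(self, model):
        return generate_cohort(model, GeneratorConfig(n=1, seed=11))[0]

    def test_ground_truth_init_is_stationary(self, model, subject):
        """Self-consistent start (soft-rendered target, noiseless
        anthropometry): the loss is zero at the truth and the fit stays put."""
        from meshcomp.silhouette import render_soft_silhouette

        ps = PoseShape(np.zeros((model.n_joints, 3)), subject.true_shape.copy())
        truth_init = InitialEstimate(pose_shape=ps, camera=subject.camera)
        cfg = FitConfig(iterations=40)
        soft_gt = render_soft_silhouette(
            forward(model, ps), subject.camera, sharpness=cfg.sharpness
        )
        res = fit_mesh(truth_init, soft_gt, subject.true_anthro, model, cfg)
        best = res.loss_trace[res.best_iteration]["total"]
        assert best <= res.loss_trace[0]["total"] + 1e-9
        assert res.loss_trace[0]["total"] < 1e-12
        assert np.abs(res.pose_shape.shape - subject.true_shape).max() < 1e-3

    def test_terms_sum_to_total_and_best_loss_monotone(self, model, subject):
        res = fit_mesh(subject.init, subject.silhouette, subject.observed_anthro,
                       model, FitConfig(iterations=30))
        for entry in res.loss_trace:
            parts = sum(v for k, v in entry.items() if k != "total")
            assert abs(parts - entry["total"]) < 1e-6
        best = np.minimum.accumulate([e["total"] for e in res.loss_trace])
        assert np.all(np.diff(best) <= 1e-12)

    def test_height_only_one_dimensional_recovery(self, model):
        """With only the height term and a stature-only basis direction, the
        1-D problem recovers the target height to < 1 mm."""
        w = LossWeights(l1=0, l2=0, l3=100.0, l4=0, l5=0, l6=0, l7=0, l8=0)
        target = _anthro(height=1.74)
        init = InitialEstimate(
            pose_shape=PoseShape.zeros(model), camera=standard_camera()
        )
        dummy = hard_rasterize(forward(model, PoseShape.zeros(model)), standard_camera())
        res = fit_mesh(init, dummy, target, model,
                       FitConfig(iterations=300, weights=w, freeze_camera=True))
        assert abs(res.measured_anthropometry["height"] - 1.74) < 1e-3

    def test_recovery_from_shrunk_init(self, model, subject):
        """Shrunk-to-mean init: high IoU and close anthropometry after the fit."""
        res = fit_mesh(subject.init, subject.silhouette, subject.observed_anthro,
                       model, FitConfig())
        assert res.final_iou >= 0.97
        obs = subject.observed_anthro
        assert abs(res.measured_anthropometry["waist"] - obs.waist_circ) / obs.waist_circ < 0.01
        assert abs(res.measured_anthropometry["hip"] - obs.hip_circ) / obs.hip_circ < 0.01

    def test_model_object_interface_matches_function(self, model, subject):
        cfg = FitConfig(iterations=10)
        a = SilhouetteFitModel(model, subject.silhouette, subject.observed_anthro,
                               subject.init).fit(cfg)
        b = fit_mesh(subject.init, subject.silhouette, subject.observed_anthro, model, cfg)
        np.testing.assert_array_equal(a.pose_shape.shape, b.pose_shape.shape)
        assert "final IoU" in a.summary()

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(l1=-1.0)
        with pytest.raises(ValueError):
            LossWeights(l1=0, l2=0, l3=0, l4=0, l5=0, l6=0, l7=0, l8=0)
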