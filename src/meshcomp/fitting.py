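"""Mesh fitting: refine pose/shape/camera against a silhouette + anthropometry.

The objective is the sum of three groups of terms, each with manually tuned
non-negative weights:

* anthropometry: squared errors of mesh waist circumference, hip
  circumference and height against the tape measurements;
* silhouette: squared pixel difference between the soft-rendered silhouette
  and the target mask, plus a 2D joint regulariser toward the initial
  estimate (weak-perspective projection of the regressed joints);
* scanbed alignment: supine-scan priors -- spine/leg rotations may not bend
  out of the scanbed plane, arm rotations are pulled toward their initial
  values, and arm joint depths are pulled to the pelvis depth plane.

Optimization is Adam over (shape, pose, camera) with per-group learning
rates and a fixed iteration budget; the best-loss iterate is returned.  The
fit is deterministic: there are no stochastic terms.

``SilhouetteFitModel`` wraps the procedure in a model-object interface:
construct from data, call ``fit()``, read the ``MeshFitResult``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .bodymodel import BodyModel, MeshInstance, PoseShape, forward_tensors, shaped_vertices_t
from .measurements import Anthropometry, circumference_t, height_t
from .multiview import ShapeGaussian
from .silhouette import (
    CameraWP,
    SilhouetteMask,
    mask_iou,
    project_points_t,
    render_soft_silhouette_t,
)

__all__ = [
    "LossWeights",
    "InitialEstimate",
    "FitConfig",
    "FitResult",
    "anthropometry_loss",
    "silhouette_loss",
    "scanbed_loss",
    "fit_mesh",
    "SilhouetteFitModel",
]


@dataclass
class LossWeights:
    """The eight manually tuned loss weights (all >= 0, at least one > 0)."""

    l1: float = 50.0  # waist circumference
    l2: float = 50.0  # hip circumference
    l3: float = 100.0  # height
    l4: float = 30.0  # silhouette pixels
    l5: float = 1e-4  # 2D joint regulariser
    l6: float = 2.0  # out-of-scanbed-plane spine/leg bending
    l7: float = 0.5  # arm pose anchoring
    l8: float = 2.0  # arm depth to pelvis plane

    def __post_init__(self):
        vals = [self.l1, self.l2, self.l3, self.l4, self.l5, self.l6, self.l7, self.l8]
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


@dataclass
class InitialEstimate:
    """Starting point for the optimizer (the initializer's output contract)."""

    pose_shape: PoseShape
    camera: CameraWP
    joints2d_init: np.ndarray | None = None  # (J, 2); regulariser target
    shape_gaussian: ShapeGaussian | None = None  # multiview pathway


@dataclass
class FitConfig:
    iterations: int = 400
    lr_shape: float = 0.03
    lr_pose: float = 0.02
    lr_cam: float = 0.3
    sharpness: float = 6.0  # px^-1
    size: tuple[int, int] = (256, 256)
    freeze_camera: bool = False
    silhouette_reduction: str = "mean"  # or "sum" (the raw printed form)
    adam_eps: float = 1e-2  # damps drift along loss-flat (under-determined) directions
    weights: LossWeights = field(default_factory=LossWeights)


@dataclass
class FitResult:
    pose_shape: PoseShape
    camera: CameraWP
    loss_trace: list[dict]
    final_iou: float
    measured_anthropometry: dict
    best_iteration: int = -1

    @property
    def shape(self) -> np.ndarray:
        return self.pose_shape.shape

    def summary(self) -> str:
        last = self.loss_trace[-1]
        lines = [
            "Silhouette fit",
            f"  iterations: {len(self.loss_trace)} (best at {self.best_iteration})",
            f"  final loss: {last['total']:.6g}",
            f"  final IoU : {self.final_iou:.4f}",
            "  measured anthropometry (m):",
        ]
        for k, v in self.measured_anthropometry.items():
            lines.append(f"    {k:>8s}: {v:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------


def anthropometry_loss(measures: dict, targets: Anthropometry, w: LossWeights):
    """w1*(waist_err)^2 + w2*(hip_err)^2 + w3*(height_err)^2 (meters^2)."""
    waist = ad.tensor(measures["waist"])
    hip = ad.tensor(measures["hip"])
    height = ad.tensor(measures["height"])
    return (
        w.l1 * (waist - targets.waist_circ) ** 2
        + w.l2 * (hip - targets.hip_circ) ** 2
        + w.l3 * (height - targets.height) ** 2
    )


def _silhouette_terms(
    verts_t: Tensor,
    joints_t: Tensor,
    cam_t: Tensor,
    s_gt: SilhouetteMask,
    j2d_init: np.ndarray,
    w: LossWeights,
    cfg: FitConfig,
):
    size = s_gt.shape
    p2 = project_points_t(verts_t, cam_t)
    pix = None
    if w.l4 > 0:
        rendered = render_soft_silhouette_t(p2, _faces_of(verts_t, cfg), size, cfg.sharpness)
        diff = rendered - s_gt.grid
        pix = (diff * diff).mean() if cfg.silhouette_reduction == "mean" else (diff * diff).sum()
        pix = w.l4 * pix
    j2d = project_points_t(joints_t, cam_t)
    jdiff = j2d - j2d_init
    joint = w.l5 * (jdiff * jdiff).sum()
    return pix, joint


def _faces_of(verts_t, cfg):  # set per-fit by fit_mesh (faces ride on the config)
    return cfg._faces


def silhouette_loss(
    mesh: MeshInstance,
    cam: CameraWP,
    s_gt: SilhouetteMask,
    j2d_init: np.ndarray,
    w: LossWeights,
    *,
    sharpness: float = 6.0,
    reduction: str = "mean",
) -> float:
    """Silhouette + joint-regulariser loss for a concrete mesh."""
    cfg = FitConfig(sharpness=sharpness, silhouette_reduction=reduction)
    cfg._faces = mesh.faces
    pix, joint = _silhouette_terms(
        ad.tensor(mesh.vertices),
        ad.tensor(mesh.joints),
        ad.tensor(cam.as_array()),
        s_gt,
        np.asarray(j2d_init, dtype=np.float64),
        w,
        cfg,
    )
    total = joint if pix is None else pix + joint
    return float(total.item())


def scanbed_loss_t(
    pose_t: Tensor,
    pose_init: np.ndarray,
    joints3d_t: Tensor,
    model: BodyModel,
    w: LossWeights,
):
    groups = model.joint_groups
    for key in ("scanbed", "arms", "arm_joints_depth"):
        if key not in groups:
            raise KeyError(f"model joint map lacks the {key!r} subset")
    scan = groups["scanbed"]
    arms = groups["arms"]
    depth_j = groups["arm_joints_depth"]
    pelvis = model.joint_names.index("pelvis") if model.joint_names else 0
    # theta^(1): components that bend out of the scanbed plane.
    # With depth = z, in-plane (on-bed) rotation is about z; x/y components tilt
    # the spine/legs out of the bed plane.
    th1 = pose_t[scan][:, :2]
    term1 = w.l6 * (th1 * th1).sum()
    darm = pose_t[arms] - pose_init[arms]
    term2 = w.l7 * (darm * darm).sum()
    dz = joints3d_t[depth_j, 2] - joints3d_t[pelvis, 2]
    term3 = w.l8 * (dz * dz).sum()
    return term1 + term2 + term3


def scanbed_loss(pose, pose_init, joints3d, model: BodyModel, w: LossWeights) -> float:
    return float(
        scanbed_loss_t(
            ad.tensor(np.asarray(pose, dtype=np.float64)),
            np.asarray(pose_init, dtype=np.float64),
            ad.tensor(np.asarray(joints3d, dtype=np.float64)),
            model,
            w,
        ).item()
    )


# ---------------------------------------------------------------------------
# the optimizer
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: list[Tensor], lrs: list[float], b1=0.9, b2=0.999, eps=1e-8):
        self.params, self.lrs = params, lrs
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lrs[i] * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def fit_mesh(
    init: InitialEstimate,
    s_gt: SilhouetteMask,
    anthro: Anthropometry,
    model: BodyModel,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Minimize the total loss over (shape, pose, camera); deterministic."""
    cfg = cfg or FitConfig()
    cfg._faces = model.faces
    w = cfg.weights
    if s_gt.shape != cfg.size:
        cfg.size = s_gt.shape

    beta = ad.tensor(np.asarray(init.pose_shape.shape, dtype=np.float64).copy(), requires_grad=True)
    theta = ad.tensor(np.asarray(init.pose_shape.pose, dtype=np.float64).copy(), requires_grad=True)
    cam = ad.tensor(init.camera.as_array(), requires_grad=not cfg.freeze_camera)
    trans = np.asarray(init.pose_shape.global_translation, dtype=np.float64)
    pose_init = np.asarray(init.pose_shape.pose, dtype=np.float64).copy()

    if init.joints2d_init is None:
        v0, j0 = forward_tensors(model, ad.tensor(pose_init), ad.tensor(beta.data), ad.tensor(trans))
        j2d_init = project_points_t(j0, ad.tensor(cam.data)).numpy()
    else:
        j2d_init = np.asarray(init.joints2d_init, dtype=np.float64)

    params = [beta, theta] + ([cam] if not cfg.freeze_camera else [])
    lrs = [cfg.lr_shape, cfg.lr_pose] + ([cfg.lr_cam] if not cfg.freeze_camera else [])
    opt = _Adam(params, lrs, eps=cfg.adam_eps)

    trace: list[dict] = []
    best = {"loss": np.inf, "beta": beta.data.copy(), "theta": theta.data.copy(),
            "cam": cam.data.copy(), "iter": -1}

    for it in range(cfg.iterations):
        opt.zero_grad()
        v_shaped = shaped_vertices_t(model, beta)
        terms: dict[str, float] = {}
        loss = None

        def _acc(name, t):
            nonlocal loss
            if t is None:
                return
            terms[name] = float(t.item())
            loss = t if loss is None else loss + t

        if w.l1 > 0 or w.l2 > 0 or w.l3 > 0:
            measures = {
                "waist": circumference_t(model, v_shaped, "waist"),
                "hip": circumference_t(model, v_shaped, "hip"),
                "height": height_t(model, beta),
            }
            _acc("anthropometry", anthropometry_loss(measures, anthro, w))
        verts_t, joints_t = forward_tensors(model, theta, beta, ad.tensor(trans))
        pix, joint = _silhouette_terms(verts_t, joints_t, cam, s_gt, j2d_init, w, cfg)
        _acc("silhouette", pix)
        _acc("joints2d", joint)
        _acc("scanbed", scanbed_loss_t(theta, pose_init, joints_t, model, w))

        total = float(loss.item())
        if not np.isfinite(total):
            bad = [k for k, v in terms.items() if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite loss in term(s) {bad} at iteration {it}")
        terms["total"] = total
        trace.append(terms)
        if total < best["loss"]:
            best.update(loss=total, beta=beta.data.copy(), theta=theta.data.copy(),
                        cam=cam.data.copy(), iter=it)
        loss.backward()
        opt.step()

    ps = PoseShape(pose=best["theta"], shape=best["beta"], global_translation=trans)
    camera = CameraWP.from_array(best["cam"])
    verts_t, joints_t = forward_tensors(
        model, ad.tensor(ps.pose), ad.tensor(ps.shape), ad.tensor(trans)
    )
    p2 = project_points_t(verts_t, ad.tensor(camera.as_array()))
    rendered = render_soft_silhouette_t(p2, model.faces, s_gt.shape, cfg.sharpness)
    final_iou = mask_iou(SilhouetteMask(np.clip(rendered.numpy(), 0, 1), s_gt.pixel_spacing), s_gt)
    v_shaped = shaped_vertices_t(model, ad.tensor(ps.shape))
    measured = {
        "height": float(height_t(model, ad.tensor(ps.shape)).item()),
        "waist": float(circumference_t(model, v_shaped, "waist").item()),
        "hip": float(circumference_t(model, v_shaped, "hip").item()),
    }
    return FitResult(
        pose_shape=ps,
        camera=camera,
        loss_trace=trace,
        final_iou=final_iou,
        measured_anthropometry=measured,
        best_iteration=best["iter"],
    )


class SilhouetteFitModel:
    """Model-object wrapper: data in the constructor, estimates from ``fit()``.

    Parameters
    ----------
    body_model : BodyModel
    silhouette : SilhouetteMask
        Target mask (binary; extract from a DXA-style image first).
    anthropometry : Anthropometry
        Tape measurements in meters/kg.
    init : InitialEstimate
        Starting pose/shape/camera (e.g. a degraded or probabilistic
        initializer output).
    """

    def __init__(self, body_model: BodyModel, silhouette: SilhouetteMask,
                 anthropometry: Anthropometry, init: InitialEstimate):
        self.body_model = body_model
        self.silhouette = silhouette
        self.anthropometry = anthropometry
        self.init = init

    def fit(self, config: FitConfig | None = None) -> FitResult:
        return fit_mesh(self.init, self.silhouette, self.anthropometry,
                        self.body_model, config)
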