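"""Synthetic cohorts: shapes, supine silhouettes, anthropometry, composition.

The generator emulates the inputs of a DXA-plus-anthropometry study so the
whole pipeline is testable without any restricted data:

* shapes are drawn from the model's Gaussian prior (one unit = one SD);
* "true" anthropometry is measured on the shaped mesh by the measurements
  module; observed anthropometry adds tape-measure noise;
* the silhouette is the hard orthographic rasterization of the supine-pose
  mesh under a standard camera;
* the ten composition metrics follow a known generative map: linear terms in
  anthropometry plus shape-coefficient terms (torso depth drives visceral
  fat, echoing its link with sagittal abdominal diameter) plus one quadratic
  waist term, with heteroscedastic noise.  Derived metrics respect the exact
  identities pbf = 100*fat/weight, almi = alm/height^2 and
  android = visceral + abdominal SCAT.

Per-subject randomness is keyed by (seed, subject index) so cohorts are
bit-reproducible and longitudinal re-realization reuses the same noise:
a zero drift reproduces phase 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bodymodel import BodyModel, PoseShape, forward
from .fitting import InitialEstimate
from .measurements import Anthropometry, mesh_anthropometry
from .multiview import ShapeGaussian
from .regressor import METRICS, CompositionRecord
from .silhouette import CameraWP, SilhouetteMask, hard_rasterize, project_points

__all__ = [
    "GeneratorConfig",
    "SyntheticSubject",
    "standard_camera",
    "generate_cohort",
    "cohort_frame",
    "generate_longitudinal",
    "degrade_initialization",
    "emit_view_gaussians",
]

# reference values the composition map is anchored at (the default template)
_REF = {"weight": 69.4, "waist_cm": 70.9, "hip_cm": 90.2, "height_m": 1.68}

#: default per-metric noise SDs (those of derived metrics are unused)
_DEFAULT_NOISE = {
    "total_fat": 1.2, "pbf": 0.0, "android_fat": 0.0, "gynoid_fat": 0.30,
    "visceral_fat": 0.18, "abd_scat": 0.15, "peripheral_fat": 0.50,
    "total_lean": 0.0, "alm": 0.40, "almi": 0.0,
}


@dataclass
class GeneratorConfig:
    n: int = 100
    seed: int = 0
    shape_prior_sd: np.ndarray | float = 1.0  # per-coefficient prior SD
    anthro_noise_sd_cm: float = 1.0  # tape error on waist/hip
    height_noise_sd_cm: float = 0.3
    weight_noise_sd_kg: float = 0.2
    sex_ratio: float = 0.5  # fraction male
    # composition-map richness: "full" = anthropometry + shape terms,
    # "anthro" = anthropometry only, "basic" = height & weight only (the
    # degenerate map under which all regressor input sets are equivalent)
    composition_effects: str = "full"
    quadratic: bool = True  # quadratic waist term (visceral fat)
    noise_scale: float = 1.0  # multiplies all composition noise SDs
    noise_sds: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    canvas: tuple[int, int] = (256, 256)
    with_silhouettes: bool = True
    with_inits: bool = True
    # initializer degradation (shrunk-to-the-prior-mean shape, perturbed pose)
    init_shrinkage: float = 0.6
    init_shape_noise_sd: float = 0.10
    init_pose_noise_sd: float = 0.03  # rad
    init_forward_lean: float = 0.15  # rad, torso tilt out of the scanbed plane


@dataclass
class SyntheticSubject:
    id: str
    true_shape: np.ndarray
    sex: str
    true_anthro: Anthropometry
    observed_anthro: Anthropometry
    composition: CompositionRecord
    silhouette: SilhouetteMask | None = None
    init: InitialEstimate | None = None
    camera: CameraWP | None = None
    noise_key: tuple = ()


def standard_camera(canvas: tuple[int, int] = (256, 256)) -> CameraWP:
    """Camera framing a ~1.9 m supine body on the canvas."""
    h, w = canvas
    s = 0.82 * min(h, w) / 1.8
    return CameraWP(scale=s, translation=np.array([w / 2.0, h / 2.0 - s * 0.88]))


def _composition_map(beta, anthro: Anthropometry, cfg: GeneratorConfig,
                     eps: np.ndarray) -> CompositionRecord:
    """The known generative map from (shape, anthropometry) to the metrics.

    ``eps`` holds one standard-normal draw per metric name (fixed per
    subject, reused across longitudinal phases).
    """
    w = anthro.weight
    h = anthro.height
    ns = {k: v * cfg.noise_scale for k, v in cfg.noise_sds.items()}

    level = cfg.composition_effects
    if level not in ("full", "anthro", "basic"):
        raise ValueError("composition_effects must be 'full', 'anthro' or 'basic'")
    if level == "basic":
        sexc = dwaist = dhip = 0.0
    else:
        sexc = anthro.sex_code
        dwaist = anthro.waist_circ * 100.0 - _REF["waist_cm"]
        dhip = anthro.hip_circ * 100.0 - _REF["hip_cm"]
    if level == "full":
        depth, waistc, limb = beta[1], beta[2], beta[4]
    else:
        depth = waistc = limb = 0.0
    quad = ((dwaist / 10.0) ** 2) if (cfg.quadratic and level == "full") else 0.0

    total_fat = (
        26.0 + 0.35 * (w - _REF["weight"]) + 0.22 * dwaist
        + 1.3 * depth + 1.1 * limb - 6.0 * sexc
        + ns["total_fat"] * eps[0]
    )
    total_fat = max(total_fat, 1.0)
    visceral = (
        0.95 + 0.045 * dwaist + 0.45 * depth + 0.28 * quad + 0.15 * sexc
        + ns["visceral_fat"] * eps[4]
    )
    visceral = max(visceral, 0.05)
    abd_scat = (
        1.35 + 0.045 * dwaist + 0.18 * waistc - 0.25 * sexc
        + ns["abd_scat"] * eps[5]
    )
    abd_scat = max(abd_scat, 0.05)
    android = visceral + abd_scat
    gynoid = (
        0.9 + 0.045 * dhip + 0.115 * total_fat + ns["gynoid_fat"] * eps[3]
    )
    gynoid = max(gynoid, 0.1)
    peripheral = max(0.40 * total_fat + 0.9 * limb + ns["peripheral_fat"] * eps[6], 0.1)
    total_lean = max(w - total_fat - 3.6, 10.0)  # mass balance minus bone-like rest
    alm = max(0.46 * total_lean + 1.1 * limb + ns["alm"] * eps[8], 1.0)
    return CompositionRecord(
        total_fat=total_fat,
        pbf=float(np.clip(100.0 * total_fat / w, 0.0, 100.0)),
        android_fat=android,
        gynoid_fat=gynoid,
        visceral_fat=visceral,
        abd_scat=abd_scat,
        peripheral_fat=peripheral,
        total_lean=total_lean,
        alm=alm,
        almi=alm / h**2,
    )


def _realize(model: BodyModel, cfg: GeneratorConfig, i: int, beta: np.ndarray,
             *, render: bool | None = None) -> SyntheticSubject:
    """Build one subject from its shape; all noise keyed by (seed, i)."""
    rng = np.random.default_rng([cfg.seed, i, 1])
    sex = "male" if rng.random() < cfg.sex_ratio else "female"
    true_anthro = mesh_anthropometry(model, beta, sex=sex)
    observed = Anthropometry(
        height=true_anthro.height + rng.normal(0, cfg.height_noise_sd_cm) / 100.0,
        waist_circ=max(true_anthro.waist_circ + rng.normal(0, cfg.anthro_noise_sd_cm) / 100.0, 0.3),
        hip_circ=max(true_anthro.hip_circ + rng.normal(0, cfg.anthro_noise_sd_cm) / 100.0, 0.3),
        weight=max(true_anthro.weight + rng.normal(0, cfg.weight_noise_sd_kg), 20.0),
        sex=sex,
    )
    eps = rng.standard_normal(len(METRICS))
    comp = _composition_map(beta, true_anthro, cfg, eps)

    cam = standard_camera(cfg.canvas)
    silhouette = None
    if cfg.with_silhouettes if render is None else render:
        mesh = forward(model, PoseShape(np.zeros((model.n_joints, 3)), beta))
        silhouette = hard_rasterize(mesh, cam, cfg.canvas)
    subject = SyntheticSubject(
        id=f"S{cfg.seed}_{i:05d}",
        true_shape=beta,
        sex=sex,
        true_anthro=true_anthro,
        observed_anthro=observed,
        composition=comp,
        silhouette=silhouette,
        camera=cam,
        noise_key=(cfg.seed, i),
    )
    if cfg.with_inits:
        subject.init = degrade_initialization(subject, cfg, model)
    return subject


def generate_cohort(model: BodyModel, cfg: GeneratorConfig) -> list[SyntheticSubject]:
    """Generate ``cfg.n`` subjects; bit-reproducible from (cfg, seed)."""
    if cfg.n < 0:
        raise ValueError("n must be >= 0")
    prior = np.broadcast_to(np.asarray(cfg.shape_prior_sd, dtype=np.float64),
                            (model.n_shape,))
    subjects = []
    for i in range(cfg.n):
        beta = np.random.default_rng([cfg.seed, i, 0]).standard_normal(model.n_shape) * prior
        subjects.append(_realize(model, cfg, i, beta))
    return subjects


def cohort_frame(subjects: list[SyntheticSubject], *, shapes: str = "true",
                 anthro: str = "observed") -> pd.DataFrame:
    """Tabulate a cohort for the regressor (features + ten targets)."""
    rows = []
    for s in subjects:
        a = s.observed_anthro if anthro == "observed" else s.true_anthro
        row = {
            "id": s.id,
            "height_cm": a.height * 100.0,
            "waist_cm": a.waist_circ * 100.0,
            "hip_cm": a.hip_circ * 100.0,
            "weight_kg": a.weight,
            "sex": s.sex,
            "sex_code": a.sex_code,
        }
        beta = s.true_shape
        for b, v in enumerate(beta):
            row[f"beta_{b}"] = v
        for m in METRICS:
            row[m] = getattr(s.composition, m)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DriftConfig:
    """Longitudinal shape drift concentrated on girth/depth directions.

    Fat-linked directions (torso depth, waist, hip) drift with per-subject
    random magnitude; lean-linked directions (stature, limb thickness) stay
    nearly unchanged, emulating cohorts whose lean mass is largely static.
    """

    girth_sd: float = 0.6  # SD of drift on waist/hip/depth coefficients
    lean_sd: float = 0.05  # SD of drift on stature/limb coefficients
    seed: int = 1


def generate_longitudinal(
    model: BodyModel,
    cohort: list[SyntheticSubject],
    drift_cfg: DriftConfig | None = None,
    cfg: GeneratorConfig | None = None,
) -> list[SyntheticSubject]:
    """Phase-2 re-realization of each subject after a shape drift.

    Subject-level noise is reused (same key), so zero drift reproduces
    phase 1 exactly and composition changes are driven by the drift.
    """
    drift_cfg = drift_cfg or DriftConfig()
    if cfg is None:
        raise ValueError("pass the GeneratorConfig used for phase 1")
    phase2 = []
    for s in cohort:
        i = s.noise_key[1]
        rng = np.random.default_rng([drift_cfg.seed, i])
        drift = np.zeros_like(s.true_shape)
        girth_dims, lean_dims = [1, 2, 3], [0, 4]
        drift[girth_dims] = rng.normal(0.0, drift_cfg.girth_sd, size=len(girth_dims))
        drift[lean_dims] = rng.normal(0.0, drift_cfg.lean_sd, size=len(lean_dims))
        phase2.append(_realize(model, cfg, i, s.true_shape + drift))
    return phase2


def degrade_initialization(
    subject: SyntheticSubject, cfg: GeneratorConfig, model: BodyModel
) -> InitialEstimate:
    """Initializer-style degraded estimate: shape shrunk toward the prior
    mean plus noise, pose perturbed with a forward-leaning torso."""
    rng = np.random.default_rng([cfg.seed, subject.noise_key[1], 2])
    beta0 = (1.0 - cfg.init_shrinkage) * subject.true_shape
    beta0 = beta0 + rng.normal(0.0, cfg.init_shape_noise_sd, size=beta0.shape)
    pose0 = rng.normal(0.0, cfg.init_pose_noise_sd, size=(model.n_joints, 3))
    if cfg.init_forward_lean > 0 and model.joint_names:
        for name in ("spine", "chest"):
            j = model.joint_names.index(name)
            pose0[j, 0] += cfg.init_forward_lean / 2.0
    ps = PoseShape(pose=pose0, shape=beta0)
    cam = subject.camera or standard_camera(cfg.canvas)
    mesh = forward(model, ps)
    j2d = project_points(mesh.joints, cam)
    var = np.full(model.n_shape, max(cfg.init_shape_noise_sd, 1e-3) ** 2)
    return InitialEstimate(
        pose_shape=ps,
        camera=CameraWP(cam.scale, cam.translation.copy()),
        joints2d_init=j2d,
        shape_gaussian=ShapeGaussian(mean=beta0.copy(), variance=var),
    )


def emit_view_gaussians(
    subject: SyntheticSubject, n_views: int, view_noise_sds, seed: int = 0
) -> list[ShapeGaussian]:
    """Per-view Gaussians around the true shape; calibrated by construction."""
    if n_views < 1:
        raise ValueError("need at least one view")
    sds = np.broadcast_to(np.asarray(view_noise_sds, dtype=np.float64), (n_views,))
    rng = np.random.default_rng([seed, subject.noise_key[1], 3])
    views = []
    for v in range(n_views):
        mean = subject.true_shape + rng.normal(0.0, sds[v], size=subject.true_shape.shape)
        views.append(ShapeGaussian(mean=mean, variance=np.full_like(mean, max(sds[v], 1e-12) ** 2)))
    return views
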