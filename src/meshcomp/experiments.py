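"""End-to-end study designs on synthetic cohorts.

Four orchestrations mirror the validation designs of silhouette-based body
composition studies:

* comparison study: regressors with nested input sets (Models A-E) trained
  on one split and scored (R^2) on held-out data;
* full pipeline: degraded initialization -> silhouette+anthropometry mesh
  fit -> composition prediction from the fitted shape, with an oracle-shapes
  upper bound (true shape coefficients) to isolate fitting error;
* change study: one regressor trained on baseline data predicts both phases
  of a longitudinal cohort; agreement is computed on within-subject deltas;
* multiview study: product-of-Gaussians fusion of noisy per-view shape
  estimates feeding the same regressor (no optimization stage).

Train/test hygiene is asserted: no test subject id enters any training
array.  Every study is reproducible from (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agreement import AgreementReport, agreement, change_analysis
from .bodymodel import BodyModel
from .fitting import FitConfig, fit_mesh
from .measurements import Anthropometry
from .multiview import fuse_views
from .regressor import (
    METRICS,
    MODEL_SPECS,
    CompositionModel,
    TrainConfig,
    features_from_frame,
)
from .synthetic import (
    DriftConfig,
    GeneratorConfig,
    cohort_frame,
    emit_view_gaussians,
    generate_cohort,
    generate_longitudinal,
)

__all__ = [
    "ExperimentSpec",
    "run_comparison_study",
    "run_full_pipeline",
    "run_change_study",
    "run_multiview_study",
]

log = logging.getLogger(__name__)


@dataclass
class ExperimentSpec:
    name: str = "default"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    fit: FitConfig | str = "oracle-shapes"
    models: tuple[str, ...] = ("A", "B", "C", "D", "E")
    splits: tuple[float, float, float] = (0.64, 0.16, 0.20)  # train/val/test
    seed: int = 0
    train_config: TrainConfig = field(default_factory=TrainConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)

    def __post_init__(self):
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        unknown = [m for m in self.models if m not in MODEL_SPECS]
        if unknown:
            raise ValueError(f"unknown model name(s): {unknown}")


def _split_frame(df: pd.DataFrame, spec: ExperimentSpec):
    """Deterministic train(+val)/test split; validation is delegated to the
    trainer as a fraction of the training block."""
    n = len(df)
    rng = np.random.default_rng([spec.seed, 17])
    perm = rng.permutation(n)
    n_test = int(round(spec.splits[2] * n))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    train_df = df.iloc[train_idx].reset_index(drop=True)
    test_df = df.iloc[test_idx].reset_index(drop=True)
    assert not set(train_df["id"]).intersection(test_df["id"]), "split leakage"
    return train_df, test_df


def _train_cfg(spec: ExperimentSpec) -> TrainConfig:
    val = spec.splits[1] / max(spec.splits[0] + spec.splits[1], 1e-12)
    return replace(spec.train_config, val_frac=val)


# ---------------------------------------------------------------------------
# comparison study (Models A-E)
# ---------------------------------------------------------------------------


def run_comparison_study(spec: ExperimentSpec, body_model: BodyModel) -> pd.DataFrame:
    """Held-out R^2 per model and metric (rows = metrics, columns = models)."""
    gen = replace(spec.generator, with_silhouettes=False, with_inits=False)
    cohort = generate_cohort(body_model, gen)
    df = cohort_frame(cohort)
    train_df, test_df = _split_frame(df, spec)
    out = {}
    for name in spec.models:
        try:
            res = CompositionModel(train_df, name, _train_cfg(spec)).fit(seed=spec.seed)
            ev = res.evaluate(test_df)
        except Exception as err:  # pragma: no cover - abort carries the name
            raise RuntimeError(f"comparison study failed for model {name}") from err
        out[name] = ev["r_squared"]
    table = pd.DataFrame(out)
    table.index.name = "metric"
    return table


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _anthro_of_row(row) -> Anthropometry:
    return Anthropometry(
        height=row["height_cm"] / 100.0,
        waist_circ=row["waist_cm"] / 100.0,
        hip_circ=row["hip_cm"] / 100.0,
        weight=row["weight_kg"],
        sex=row["sex"],
    )


def run_full_pipeline(spec: ExperimentSpec, body_model: BodyModel,
                      n_test: int | None = None) -> dict:
    """Fit test subjects from degraded inits, predict composition from the
    fitted shapes, and compare against the oracle-shapes upper bound."""
    if isinstance(spec.fit, str):
        raise ValueError("run_full_pipeline needs a real FitConfig in spec.fit")
    cohort = generate_cohort(body_model, spec.generator)
    df = cohort_frame(cohort)
    train_df, test_df = _split_frame(df, spec)
    if n_test is not None:
        test_df = test_df.iloc[:n_test].reset_index(drop=True)
    res = CompositionModel(train_df, "E", _train_cfg(spec)).fit(seed=spec.seed)

    by_id = {s.id: s for s in cohort}
    fitted_rows, failures = [], []
    for _, row in test_df.iterrows():
        s = by_id[row["id"]]
        try:
            fit = fit_mesh(s.init, s.silhouette, s.observed_anthro, body_model, spec.fit)
        except FloatingPointError as err:
            failures.append((s.id, str(err)))
            continue
        new = row.copy()
        for b, v in enumerate(fit.pose_shape.shape):
            new[f"beta_{b}"] = v
        new["final_iou"] = fit.final_iou
        fitted_rows.append(new)
    if failures:
        log.warning("excluded %d failed fits: %s", len(failures), failures)
    fitted_df = pd.DataFrame(fitted_rows).reset_index(drop=True)
    kept = test_df[test_df["id"].isin(fitted_df["id"])].reset_index(drop=True)

    pred_fit = res.predict(fitted_df)
    pred_oracle = res.predict(kept)
    truth = kept[METRICS].to_numpy(dtype=np.float64)
    reports_fit = {m: agreement(pred_fit[:, i], truth[:, i]) for i, m in enumerate(METRICS)}
    reports_oracle = {m: agreement(pred_oracle[:, i], truth[:, i]) for i, m in enumerate(METRICS)}
    return {
        "results": res,
        "fitted": fitted_df,
        "test": kept,
        "n_failures": len(failures),
        "agreement_fitted": reports_fit,
        "agreement_oracle": reports_oracle,
        "shape_error_fitted": np.mean(
            np.abs(
                fitted_df[[f"beta_{b}" for b in range(body_model.n_shape)]].to_numpy()
                - np.stack([by_id[i].true_shape for i in fitted_df["id"]])
            ),
            axis=0,
        ),
    }


# ---------------------------------------------------------------------------
# longitudinal change study
# ---------------------------------------------------------------------------


def run_change_study(spec: ExperimentSpec, body_model: BodyModel) -> dict:
    """Train on baseline (phase-1) data only, predict both phases, and
    score agreement on within-subject changes (oracle-shapes pathway)."""
    gen = replace(spec.generator, with_silhouettes=False, with_inits=False)
    phase1 = generate_cohort(body_model, gen)
    phase2 = generate_longitudinal(body_model, phase1, spec.drift, gen)
    df1, df2 = cohort_frame(phase1), cohort_frame(phase2)
    train_df, test1 = _split_frame(df1, spec)
    test2 = df2[df2["id"].isin(test1["id"])].set_index("id").loc[test1["id"]].reset_index()
    res = CompositionModel(train_df, "E", _train_cfg(spec)).fit(seed=spec.seed)
    pred1, pred2 = res.predict(test1), res.predict(test2)
    t1 = test1[METRICS].to_numpy(dtype=np.float64)
    t2 = test2[METRICS].to_numpy(dtype=np.float64)
    reports = {
        m: change_analysis(pred1[:, i], t1[:, i], pred2[:, i], t2[:, i],
                           ids1=test1["id"], ids2=test2["id"])
        for i, m in enumerate(METRICS)
    }
    return {"results": res, "change_agreement": reports,
            "test_phase1": test1, "test_phase2": test2}


# ---------------------------------------------------------------------------
# multiview study
# ---------------------------------------------------------------------------


def run_multiview_study(spec: ExperimentSpec, body_model: BodyModel,
                        n_views: int = 4, view_noise_sd: float = 0.5) -> dict:
    """Fused-shape predictions vs single-view predictions on held-out data."""
    gen = replace(spec.generator, with_silhouettes=False, with_inits=False)
    cohort = generate_cohort(body_model, gen)
    df = cohort_frame(cohort)
    train_df, test_df = _split_frame(df, spec)
    res = CompositionModel(train_df, "E", _train_cfg(spec)).fit(seed=spec.seed)
    by_id = {s.id: s for s in cohort}

    def predict_with_shapes(frame, shapes):
        work = frame.copy()
        for b in range(body_model.n_shape):
            work[f"beta_{b}"] = [sh[b] for sh in shapes]
        return res.predict(work)

    fused_shapes, single_shapes, shape_err = [], [], {"fused": [], "single": []}
    for sid in test_df["id"]:
        s = by_id[sid]
        views = emit_view_gaussians(s, n_views, view_noise_sd, seed=spec.seed)
        fused = fuse_views(views)
        fused_shapes.append(fused.mean)
        single_shapes.append(views[0].mean)
        shape_err["fused"].append(fused.mean - s.true_shape)
        shape_err["single"].append(views[0].mean - s.true_shape)
    pred_fused = predict_with_shapes(test_df, fused_shapes)
    pred_single = predict_with_shapes(test_df, single_shapes)
    truth = test_df[METRICS].to_numpy(dtype=np.float64)
    return {
        "results": res,
        "agreement_fused": {m: agreement(pred_fused[:, i], truth[:, i])
                            for i, m in enumerate(METRICS)},
        "agreement_single": {m: agreement(pred_single[:, i], truth[:, i])
                             for i, m in enumerate(METRICS)},
        "shape_rmse_fused": float(np.sqrt(np.mean(np.square(shape_err["fused"])))),
        "shape_rmse_single": float(np.sqrt(np.mean(np.square(shape_err["single"])))),
    }
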