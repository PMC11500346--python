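"""Body-composition regression from shape coefficients + anthropometry.

A single small feed-forward network (~16k parameters, two residual hidden
layers, 10 outputs) maps the feature vector to all ten total/regional
composition metrics at once.  The multi-task loss is weighted by learned
homoscedastic (per-metric) uncertainties:

    L(W, sigma) = sum_i MSE_i / (2 sigma_i^2) + sum_i log sigma_i

so that metrics on different scales (kg, %, kg/m^2) weight themselves; in
addition, targets are standardized internally and de-standardized at
prediction time.  An ordinary-least-squares baseline with the same feature
interface is provided for comparison studies.

``CompositionModel(df, spec).fit()`` is the model-object interface; the
functional operations (``make_features``, ``train_regressor``, ...) are the
underlying primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .measurements import Anthropometry

__all__ = [
    "METRICS",
    "CompositionRecord",
    "FeatureSpec",
    "MODEL_SPECS",
    "make_features",
    "NetConfig",
    "TrainConfig",
    "build_regressor",
    "homoscedastic_loss",
    "train_regressor",
    "predict_composition",
    "fit_linear_baseline",
    "CompositionModel",
    "CompositionResults",
]

#: the ten DXA-style metrics, in canonical order
METRICS = [
    "total_fat",       # kg
    "pbf",             # %
    "android_fat",     # kg
    "gynoid_fat",      # kg
    "visceral_fat",    # kg
    "abd_scat",        # kg
    "peripheral_fat",  # kg
    "total_lean",      # kg
    "alm",             # kg
    "almi",            # kg/m^2
]


@dataclass
class CompositionRecord:
    """Ten total/regional composition metrics for one subject."""

    total_fat: float
    pbf: float
    android_fat: float
    gynoid_fat: float
    visceral_fat: float
    abd_scat: float
    peripheral_fat: float
    total_lean: float
    alm: float
    almi: float

    def __post_init__(self):
        masses = [self.total_fat, self.android_fat, self.gynoid_fat, self.visceral_fat,
                  self.abd_scat, self.peripheral_fat, self.total_lean, self.alm]
        if any(m < 0 for m in masses):
            raise ValueError("mass metrics must be non-negative")
        if not 0.0 <= self.pbf <= 100.0:
            raise ValueError("percentage body fat must lie in [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in METRICS])

    @classmethod
    def from_array(cls, arr) -> "CompositionRecord":
        return cls(**{m: float(v) for m, v in zip(METRICS, arr)})


# ---------------------------------------------------------------------------
# feature assembly (the comparison study's Models A-E)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    include_waist: bool = False
    include_hip: bool = False
    include_shape: bool = False
    include_bmi: bool = False
    include_sex: bool = False
    method: str = "network"  # or "linear"

    def columns(self, n_shape: int) -> list[str]:
        cols = ["height_m", "weight_kg"]
        if self.include_waist:
            cols.append("waist_m")
        if self.include_hip:
            cols.append("hip_m")
        if self.include_shape:
            cols += [f"beta_{i}" for i in range(n_shape)]
        if self.include_bmi:
            cols.append("bmi")
        if self.include_sex:
            cols.append("sex_code")
        return cols


#: Model A: height+weight; B: +waist; C: +waist+hip; D: linear on shape
#: features; E: the network on shape features (shape, height, weight, BMI, sex)
MODEL_SPECS: dict[str, FeatureSpec] = {
    "A": FeatureSpec("A"),
    "B": FeatureSpec("B", include_waist=True),
    "C": FeatureSpec("C", include_waist=True, include_hip=True),
    "D": FeatureSpec("D", include_shape=True, include_bmi=True, include_sex=True,
                     method="linear"),
    "E": FeatureSpec("E", include_shape=True, include_bmi=True, include_sex=True),
}


def make_features(shape, anthro: Anthropometry, spec: FeatureSpec | str) -> np.ndarray:
    """Assemble the feature vector for one subject; BMI is always computed."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    feats = [anthro.height, anthro.weight]
    if spec.include_waist:
        feats.append(anthro.waist_circ)
    if spec.include_hip:
        feats.append(anthro.hip_circ)
    if spec.include_shape:
        shape = np.asarray(shape, dtype=np.float64)
        if shape.ndim != 1:
            raise ValueError("shape coefficients must be a vector")
        feats.extend(shape.tolist())
    if spec.include_bmi:
        feats.append(anthro.bmi)
    if spec.include_sex:
        feats.append(anthro.sex_code)
    return np.array(feats)


def features_from_frame(df: pd.DataFrame, spec: FeatureSpec, n_shape: int) -> np.ndarray:
    cols = spec.columns(n_shape)
    work = df.copy()
    if "height_m" not in work:
        work["height_m"] = work["height_cm"] / 100.0
    if "waist_m" not in work and "waist_cm" in work:
        work["waist_m"] = work["waist_cm"] / 100.0
    if "hip_m" not in work and "hip_cm" in work:
        work["hip_m"] = work["hip_cm"] / 100.0
    if spec.include_bmi and "bmi" not in work:
        work["bmi"] = work["weight_kg"] / work["height_m"] ** 2
    missing = [c for c in cols if c not in work]
    if missing:
        raise KeyError(f"cohort table lacks feature column(s) {missing} for spec {spec.name}")
    return work[cols].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


@dataclass
class NetConfig:
    hidden: int = 80
    n_residual: int = 2  # residual hidden layers after the input layer
    dropout: float = 0.1


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.01
    batch_size: int = 256
    val_frac: float = 0.2
    net: NetConfig = field(default_factory=NetConfig)


@dataclass
class TrainedRegressor:
    """Weights + per-metric uncertainties + normalization statistics."""

    weights: dict[str, np.ndarray]
    log_sigmas: np.ndarray  # (10,)
    feature_spec: FeatureSpec
    n_shape: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    net: NetConfig = field(default_factory=NetConfig)
    history: dict = field(default_factory=dict)

    @property
    def sigmas(self) -> np.ndarray:
        return np.exp(self.log_sigmas)

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights.values()))


def _init_weights(n_in: int, cfg: NetConfig, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    h = cfg.hidden

    def glorot(a, b):
        return rng.normal(0.0, np.sqrt(2.0 / (a + b)), size=(a, b))

    weights = {"W0": glorot(n_in, h), "b0": np.zeros(h)}
    for k in range(cfg.n_residual):
        weights[f"W{k + 1}"] = glorot(h, h)
        weights[f"b{k + 1}"] = np.zeros(h)
    weights["Wout"] = glorot(h, len(METRICS))
    weights["bout"] = np.zeros(len(METRICS))
    return weights


def build_regressor(
    cfg: NetConfig | None = None,
    seed: int = 0,
    *,
    feature_spec: FeatureSpec | str = "E",
    n_shape: int = 10,
) -> TrainedRegressor:
    """Deterministically initialized (untrained) network.

    The default width keeps the trainable parameter count near 16k; a count
    outside [14k, 18k] logs a warning.
    """
    import logging

    cfg = cfg or NetConfig()
    if isinstance(feature_spec, str):
        feature_spec = MODEL_SPECS[feature_spec]
    n_in = len(feature_spec.columns(n_shape))
    model = TrainedRegressor(
        weights=_init_weights(n_in, cfg, seed),
        log_sigmas=np.zeros(len(METRICS)),
        feature_spec=feature_spec,
        n_shape=n_shape,
        x_mean=np.zeros(n_in),
        x_std=np.ones(n_in),
        y_mean=np.zeros(len(METRICS)),
        y_std=np.ones(len(METRICS)),
        net=cfg,
    )
    if not 14_000 <= model.n_parameters <= 18_000:
        logging.getLogger(__name__).warning(
            "regressor has %d parameters, outside the ~16k design band",
            model.n_parameters,
        )
    return model


def _forward_net(weights: dict, x: Tensor, cfg: NetConfig,
                 dropout_rng: np.random.Generator | None = None) -> Tensor:
    """x: (n, d) standardized features -> (n, 10) standardized predictions.

    The first two hidden layers carry identity skip connections; dropout
    (inverted) is applied to hidden activations only when a generator is
    passed (training mode).
    """
    def drop(t: Tensor) -> Tensor:
        if dropout_rng is None or cfg.dropout <= 0:
            return t
        keep = 1.0 - cfg.dropout
        mask = (dropout_rng.random(t.shape) < keep).astype(np.float64) / keep
        return t * mask

    h = drop((x @ weights["W0"] + weights["b0"]).relu())
    for k in range(cfg.n_residual):
        z = (h @ weights[f"W{k + 1}"] + weights[f"b{k + 1}"]).relu()
        h = drop(z) + h  # identity skip
    return h @ weights["Wout"] + weights["bout"]


def homoscedastic_loss(pred, target, log_sigmas) -> Tensor:
    """sum_i [ MSE_i / (2 sigma_i^2) + log sigma_i ]; differentiable in all args."""
    pred, target, log_sigmas = ad.tensor(pred), ad.tensor(target), ad.tensor(log_sigmas)
    diff = pred - target
    mse = (diff * diff).mean(axis=0)  # (10,)
    inv_two_var = 0.5 * (log_sigmas * -2.0).exp()
    return (mse * inv_two_var).sum() + log_sigmas.sum()


def _prepare_xy(train: pd.DataFrame, spec: FeatureSpec, n_shape: int):
    y = train[METRICS].to_numpy(dtype=np.float64)
    bad = np.where(~np.isfinite(y).all(axis=1))[0]
    if len(bad):
        ids = train.index[bad].tolist()[:10]
        raise ValueError(f"non-finite composition targets in rows {ids}")
    x = features_from_frame(train, spec, n_shape)
    return x, y


def train_regressor(
    train: pd.DataFrame,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    *,
    spec: FeatureSpec | str = "E",
    n_shape: int | None = None,
) -> TrainedRegressor:
    """Adam, 100 epochs, lr 0.01; best-validation-epoch weights are returned.

    Features and targets are standardized on the training split; the learned
    per-metric sigmas therefore live on the standardized target scale.
    Fully reproducible from (cfg, seed).
    """
    cfg = cfg or TrainConfig()
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    if n_shape is None:
        n_shape = len([c for c in train.columns if c.startswith("beta_")])
    x, y = _prepare_xy(train, spec, n_shape)
    n = len(x)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_frac * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    x_mean, x_std = x[tr_idx].mean(axis=0), x[tr_idx].std(axis=0)
    x_std[x_std < 1e-12] = 1.0
    y_mean, y_std = y[tr_idx].mean(axis=0), y[tr_idx].std(axis=0)
    y_std[y_std < 1e-12] = 1.0
    xs, ys = (x - x_mean) / x_std, (y - y_mean) / y_std

    model = build_regressor(cfg.net, seed, feature_spec=spec, n_shape=n_shape)
    params = {k: ad.tensor(v, requires_grad=True) for k, v in model.weights.items()}
    log_sig = ad.tensor(np.zeros(len(METRICS)), requires_grad=True)
    plist = list(params.values()) + [log_sig]

    from .fitting import _Adam

    opt = _Adam(plist, [cfg.learning_rate] * len(plist))
    drop_rng = np.random.default_rng(rng.integers(2**31))
    xv, yv = xs[val_idx], ys[val_idx]

    best_val, best_state, best_sig = np.inf, None, None
    history = {"train_loss": [], "val_mse": []}
    n_tr = len(tr_idx)
    for epoch in range(cfg.epochs):
        order = np.random.default_rng([seed, epoch]).permutation(n_tr)
        ep_loss = 0.0
        for start in range(0, n_tr, cfg.batch_size):
            idx = tr_idx[order[start:start + cfg.batch_size]]
            xb = ad.tensor(xs[idx])
            yb = ys[idx]
            opt.zero_grad()
            pred = _forward_net(params, xb, cfg.net, dropout_rng=drop_rng)
            loss = homoscedastic_loss(pred, yb, log_sig)
            loss.backward()
            opt.step()
            ep_loss += loss.item()
        pv = _forward_net(params, ad.tensor(xv), cfg.net).numpy()
        val_mse = float(np.mean((pv - yv) ** 2))
        history["train_loss"].append(ep_loss / max(1, -(-n_tr // cfg.batch_size)))
        history["val_mse"].append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_state = {k: v.data.copy() for k, v in params.items()}
            best_sig = log_sig.data.copy()

    model.weights = best_state
    model.log_sigmas = best_sig
    model.x_mean, model.x_std = x_mean, x_std
    model.y_mean, model.y_std = y_mean, y_std
    model.history = history
    return model


def predict_composition(model: TrainedRegressor, features, *, clamp_pbf: bool = True):
    """Predict the ten metrics for one feature vector or a feature matrix."""
    feats = np.asarray(features, dtype=np.float64)
    single = feats.ndim == 1
    if single:
        feats = feats[None, :]
    expected = len(model.feature_spec.columns(model.n_shape))
    if feats.shape[1] != expected:
        raise ValueError(
            f"feature length {feats.shape[1]} does not match spec "
            f"{model.feature_spec.name} (expects {expected})"
        )
    xs = (feats - model.x_mean) / model.x_std
    params = {k: ad.tensor(v) for k, v in model.weights.items()}
    pred = _forward_net(params, ad.tensor(xs), model.net).numpy()
    pred = pred * model.y_std + model.y_mean
    if clamp_pbf:
        i = METRICS.index("pbf")
        pred[:, i] = np.clip(pred[:, i], 0.0, 100.0)
    if single:
        return CompositionRecord.from_array(np.maximum(pred[0], np.where(
            [m != "pbf" for m in METRICS], 0.0, -np.inf)))
    return pred


# ---------------------------------------------------------------------------
# linear baseline (Model D)
# ---------------------------------------------------------------------------


@dataclass
class LinearBaseline:
    coef: np.ndarray  # (d+1, 10) with intercept row first
    feature_spec: FeatureSpec
    n_shape: int

    def predict(self, features) -> np.ndarray:
        feats = np.asarray(features, dtype=np.float64)
        single = feats.ndim == 1
        if single:
            feats = feats[None, :]
        design = np.concatenate([np.ones((len(feats), 1)), feats], axis=1)
        out = design @ self.coef
        return out[0] if single else out


def fit_linear_baseline(
    train: pd.DataFrame, spec: FeatureSpec | str = "D", *, n_shape: int | None = None
) -> LinearBaseline:
    """Ordinary least squares per metric on the spec'd features."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    if n_shape is None:
        n_shape = len([c for c in train.columns if c.startswith("beta_")])
    x, y = _prepare_xy(train, spec, n_shape)
    design = np.concatenate([np.ones((len(x), 1)), x], axis=1)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        cols = ["intercept"] + spec.columns(n_shape)
        # identify a collinear column by leave-one-out rank
        bad = [c for i, c in enumerate(cols)
               if np.linalg.matrix_rank(np.delete(design, i, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearBaseline(coef=coef, feature_spec=spec, n_shape=n_shape)


# ---------------------------------------------------------------------------
# model-object interface
# ---------------------------------------------------------------------------


class CompositionModel:
    """Composition regression on a cohort table (statsmodels-style).

    Parameters
    ----------
    cohort : DataFrame with anthropometry columns (height_cm or height_m,
        weight_kg, optionally waist/hip, sex_code), ``beta_*`` shape columns,
        and the ten metric columns.
    spec : feature specification or one of the comparison-study names "A".."E".
    """

    def __init__(self, cohort: pd.DataFrame, spec: FeatureSpec | str = "E",
                 train_config: TrainConfig | None = None):
        self.cohort = cohort
        self.spec = MODEL_SPECS[spec] if isinstance(spec, str) else spec
        self.train_config = train_config or TrainConfig()
        self.n_shape = len([c for c in cohort.columns if c.startswith("beta_")])

    def fit(self, seed: int = 0) -> "CompositionResults":
        if self.spec.method == "linear":
            est = fit_linear_baseline(self.cohort, self.spec, n_shape=self.n_shape)
        else:
            est = train_regressor(self.cohort, self.train_config, seed,
                                  spec=self.spec, n_shape=self.n_shape)
        return CompositionResults(self, est)


class CompositionResults:
    """Fitted composition model: predictions, uncertainties, summary table."""

    def __init__(self, model: CompositionModel, estimator):
        self.model = model
        self.estimator = estimator

    @property
    def is_linear(self) -> bool:
        return isinstance(self.estimator, LinearBaseline)

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        x = features_from_frame(cohort, self.model.spec, self.model.n_shape)
        if self.is_linear:
            return self.estimator.predict(x)
        return predict_composition(self.estimator, x)

    def evaluate(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Per-metric agreement between predictions and the table's targets."""
        from .agreement import agreement

        pred = self.predict(cohort)
        truth = cohort[METRICS].to_numpy(dtype=np.float64)
        rows = []
        for i, m in enumerate(METRICS):
            rep = agreement(pred[:, i], truth[:, i])
            rows.append({"metric": m, "r": rep.pearson_r, "r_squared": rep.r_squared,
                         "rmse": rep.rmse, "bias": rep.bias})
        return pd.DataFrame(rows).set_index("metric")

    def summary(self) -> str:
        kind = "linear (OLS)" if self.is_linear else "network"
        lines = [f"Composition model {self.model.spec.name} [{kind}]"]
        if not self.is_linear:
            lines.append(f"  parameters: {self.estimator.n_parameters}")
            lines.append("  learned per-metric sigma (standardized targets):")
            for m, s in zip(METRICS, self.estimator.sigmas):
                lines.append(f"    {m:>15s}: {s:.3f}")
        ev = self.evaluate(self.model.cohort)
        lines.append("  in-sample agreement:")
        for m, row in ev.iterrows():
            lines.append(
                f"    {m:>15s}: r2={row.r_squared:.3f} rmse={row.rmse:.3f} bias={row.bias:+.3f}"
            )
        return "\n".join(lines)
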