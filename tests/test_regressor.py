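"""Feature assembly, the residual network, the homoscedastic loss, OLS baseline."""

import numpy as np
import pandas as pd
import pytest

from meshcomp import autodiff as ad
from meshcomp.measurements import Anthropometry
from meshcomp.regressor import (
    METRICS,
    MODEL_SPECS,
    CompositionModel,
    CompositionRecord,
    NetConfig,
    TrainConfig,
    build_regressor,
    features_from_frame,
    fit_linear_baseline,
    homoscedastic_loss,
    make_features,
    predict_composition,
    train_regressor,
)


def _anthro(sex="male"):
    return Anthropometry(height=1.70, waist_circ=0.80, hip_circ=0.95, weight=77.6, sex=sex)


def linear_cohort(n=1500, n_shape=10, seed=0, noise=None, coef_seed=3):
    """Cohort whose targets are a known linear map of the Model-E features."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "height_cm": rng.normal(170, 8, n),
            "weight_kg": rng.normal(72, 10, n),
            "sex_code": rng.integers(0, 2, n).astype(float),
        }
    )
    for b in range(n_shape):
        df[f"beta_{b}"] = rng.normal(0, 1, n)
    X = features_from_frame(df, MODEL_SPECS["E"], n_shape)
    C = np.random.default_rng(coef_seed).normal(0, 1, (X.shape[1], len(METRICS)))
    Y = X @ C
    Y = Y / Y.std(axis=0) * 5.0  # comparable signal scale per metric
    if noise is not None:
        Y = Y + rng.normal(0, 1, Y.shape) * np.asarray(noise)
    for i, m in enumerate(METRICS):
        df[m] = Y[:, i]
    return df, X, Y


class TestFeatures:
    def test_bmi_computed_from_weight_and_height(self):
        f = make_features(np.zeros(10), _anthro(), "E")
        bmi = f[-2]
        assert abs(bmi - 77.6 / 1.70**2) < 1e-9
        assert abs(bmi - 26.85) < 0.01

    def test_spec_feature_lengths(self):
        a = _anthro()
        assert len(make_features(None, a, "A")) == 2
        assert len(make_features(None, a, "B")) == 3
        assert len(make_features(None, a, "C")) == 4
        assert len(make_features(np.zeros(10), a, "E")) == 14

    def test_shape_required_for_model_e(self):
        with pytest.raises(ValueError):
            make_features(np.zeros((2, 5)), _anthro(), "E")


class TestNetwork:
    def test_parameter_count_in_16k_band(self):
        model = build_regressor(NetConfig(), seed=0)
        assert 14_000 <= model.n_parameters <= 18_000

    def test_deterministic_init(self):
        a = build_regressor(NetConfig(), seed=5)
        b = build_regressor(NetConfig(), seed=5)
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])

    def test_residual_skip_passes_input(self):
        """Zeroing a residual block's weights must not zero its output."""
        from meshcomp.regressor import _forward_net

        model = build_regressor(NetConfig(), seed=0)
        w = {k: v.copy() for k, v in model.weights.items()}
        w["W1"][:] = 0.0
        w["W2"][:] = 0.0
        x = ad.tensor(np.random.default_rng(0).normal(size=(4, 14)))
        out = _forward_net({k: ad.tensor(v) for k, v in w.items()}, x, model.net)
        assert np.abs(out.numpy()).max() > 0.0

    def test_off_band_width_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            build_regressor(NetConfig(hidden=8), seed=0)
        assert any("16k" in r.message for r in caplog.records)


class TestHomoscedasticLoss:
    def test_sigma_one_equals_half_sum_mse(self, rng):
        pred = rng.normal(size=(20, 10))
        target = rng.normal(size=(20, 10))
        val = float(homoscedastic_loss(pred, target, np.zeros(10)).item())
        mse = ((pred - target) ** 2).mean(axis=0)
        assert abs(val - 0.5 * mse.sum()) < 1e-12

    def test_perfect_prediction_sigma_one_is_zero(self):
        x = np.ones((5, 10))
        assert float(homoscedastic_loss(x, x, np.zeros(10)).item()) == 0.0

    def test_optimal_sigma_is_rmse_and_stationary(self, rng):
        """For fixed residuals the loss is minimized at sigma_i = RMSE_i, where
        the gradient w.r.t. log sigma vanishes exactly."""
        pred = rng.normal(size=(50, 10))
        target = rng.normal(size=(50, 10))
        mse = ((pred - target) ** 2).mean(axis=0)
        ls_opt = 0.5 * np.log(mse)
        t = ad.tensor(ls_opt.copy(), requires_grad=True)
        homoscedastic_loss(pred, target, t).backward()
        assert np.abs(t.grad).max() < 1e-12
        # analytic minimum value: sum_i (1/2 + log RMSE_i)
        val = float(homoscedastic_loss(pred, target, ls_opt).item())
        assert abs(val - (0.5 + 0.5 * np.log(mse)).sum()) < 1e-12
        # any other sigma does worse
        assert float(homoscedastic_loss(pred, target, ls_opt + 0.3).item()) > val


class TestTraining:
    def test_linear_map_recovered(self):
        """Noiseless linear cohort: R^2 > 0.999 per metric (no dropout --
        the task is noiseless so the regularizer is off for this design)."""
        df, X, Y = linear_cohort(n=1500)
        model = train_regressor(df, TrainConfig(net=NetConfig(dropout=0.0)), seed=1)
        pred = predict_composition(model, X, clamp_pbf=False)
        for i in range(len(METRICS)):
            r2 = 1 - np.var(pred[:, i] - Y[:, i]) / np.var(Y[:, i])
            assert r2 > 0.999

    def test_sigma_ordering_matches_injected_noise(self):
        noise = np.zeros(len(METRICS))
        iv, ig, il = METRICS.index("visceral_fat"), METRICS.index("gynoid_fat"), METRICS.index("total_lean")
        noise[iv], noise[ig], noise[il] = 3.0, 1.5, 0.5
        df, X, Y = linear_cohort(n=1500, noise=noise, seed=4)
        model = train_regressor(df, TrainConfig(net=NetConfig(dropout=0.0)), seed=2)
        s = model.sigmas
        assert s[iv] > s[ig] > s[il]

    def test_reproducible_given_seed(self):
        df, _, _ = linear_cohort(n=400)
        a = train_regressor(df, TrainConfig(epochs=5), seed=9)
        b = train_regressor(df, TrainConfig(epochs=5), seed=9)
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])
        np.testing.assert_array_equal(a.log_sigmas, b.log_sigmas)

    def test_nan_targets_rejected_with_row_ids(self):
        df, _, _ = linear_cohort(n=50)
        df.loc[7, "total_fat"] = np.nan
        with pytest.raises(ValueError, match="7"):
            train_regressor(df, TrainConfig(epochs=1), seed=0)

    def test_standardization_affine_invariance(self):
        """Rescaling raw features leaves de-standardized predictions unchanged."""
        df, X, _ = linear_cohort(n=400)
        m1 = train_regressor(df, TrainConfig(epochs=10, net=NetConfig(dropout=0.0)), seed=3)
        p1 = predict_composition(m1, X, clamp_pbf=False)
        df2 = df.copy()
        # affine rescaling of a raw feature (not one that feeds derived BMI)
        df2["beta_3"] = df2["beta_3"] * 2.0 - 10.0
        m2 = train_regressor(df2, TrainConfig(epochs=10, net=NetConfig(dropout=0.0)), seed=3)
        X2 = features_from_frame(df2, MODEL_SPECS["E"], 10)
        p2 = predict_composition(m2, X2, clamp_pbf=False)
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestPredict:
    def test_training_row_recovered_on_noiseless_cohort(self):
        df, X, Y = linear_cohort(n=1500)
        model = train_regressor(df, TrainConfig(net=NetConfig(dropout=0.0)), seed=1)
        pred = predict_composition(model, X[:1], clamp_pbf=False)
        assert abs(pred[0, 0] - Y[0, 0]) < 0.5  # kg-scale agreement on a training row

    def test_duplicate_features_identical_outputs(self):
        df, X, _ = linear_cohort(n=300)
        model = train_regressor(df, TrainConfig(epochs=5), seed=0)
        a = predict_composition(model, X[:3], clamp_pbf=False)
        b = predict_composition(model, X[:3].copy(), clamp_pbf=False)
        np.testing.assert_array_equal(a, b)

    def test_spec_mismatch_rejected(self):
        df, _, _ = linear_cohort(n=200)
        model = train_regressor(df, TrainConfig(epochs=2), seed=0)
        with pytest.raises(ValueError, match="feature length"):
            predict_composition(model, np.zeros(3))


class TestLinearBaseline:
    def test_exact_recovery_of_generating_coefficients(self):
        df, X, Y = linear_cohort(n=800)
        baseline = fit_linear_baseline(df, "D")
        pred = baseline.predict(features_from_frame(df, MODEL_SPECS["D"], 10))
        np.testing.assert_allclose(pred, Y, atol=1e-8)

    def test_intercept_only_predicts_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"height_cm": np.full(50, 170.0), "weight_kg": np.full(50, 70.0)})
        for m in METRICS:
            df[m] = rng.normal(10, 2, 50)
        from meshcomp.regressor import FeatureSpec

        # constant features are collinear with the intercept
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_baseline(df, FeatureSpec("hw"))

    def test_network_beats_linear_on_quadratic_generator(self):
        df, X, Y = linear_cohort(n=2000)
        yq = (X[:, 2] ** 2) * 3.0 + X @ np.random.default_rng(1).normal(0, 1, X.shape[1])
        df = df.copy()
        df["visceral_fat"] = yq
        net = CompositionModel(df, "E", TrainConfig(net=NetConfig(dropout=0.0))).fit(seed=0)
        lin = CompositionModel(df, "D").fit(seed=0)
        r2_net = net.evaluate(df).loc["visceral_fat", "r_squared"]
        r2_lin = lin.evaluate(df).loc["visceral_fat", "r_squared"]
        assert r2_net > r2_lin

    def test_same_predict_interface(self):
        df, X, _ = linear_cohort(n=300)
        res = CompositionModel(df, "D").fit()
        out = res.predict(df)
        assert out.shape == (300, len(METRICS))
        assert "linear" in res.summary()


class TestCompositionRecord:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            CompositionRecord(-1, 30, 2, 4, 1, 1, 10, 48, 22, 7.6)
        with pytest.raises(ValueError):
            CompositionRecord(26, 130, 2, 4, 1, 1, 10, 48, 22, 7.6)

    def test_array_roundtrip(self):
        rec = CompositionRecord(26.4, 33.5, 2.3, 4.4, 1.0, 1.4, 11.6, 48.8, 22.3, 7.6)
        back = CompositionRecord.from_array(rec.as_array())
        assert rec == back
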