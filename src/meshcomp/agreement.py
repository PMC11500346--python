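"""Agreement statistics: Bland-Altman bias and limits of agreement, RMSE,
Pearson r / R-squared, and paired t-tests; plus longitudinal change analysis.

Conventions follow common body-composition validation practice: limits of
agreement are the plain mean bias +/- 1.96 * SD of the paired differences
(sample SD, n-1 denominator); in Bland-Altman plots the x-axis carries the
*reference* value, not the pair mean; R^2 is reported as the squared Pearson
correlation between predicted and measured values (an alternative
1 - SSE/SST definition is available, the two differ for biased predictors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "agreement",
    "bland_altman_points",
    "change_analysis",
    "bland_altman_plot",
    "scatter_plot",
]


@dataclass
class AgreementReport:
    n: int
    bias: float
    loa_low: float
    loa_high: float
    rmse: float
    pearson_r: float  # nan when undefined (zero variance)
    r_squared: float
    p_bias: float

    def rounded(self) -> dict:
        """Table-style rounding (biases/LoA/r to 2 decimals)."""
        return {
            "n": self.n,
            "bias": round(self.bias, 2),
            "loa": (round(self.loa_low, 2), round(self.loa_high, 2)),
            "rmse": round(self.rmse, 2),
            "r": round(self.pearson_r, 2) if np.isfinite(self.pearson_r) else None,
        }


def agreement(pred, truth, *, r2_definition: str = "pearson") -> AgreementReport:
    """Bland-Altman + correlation + paired-t agreement of pred vs truth.

    ``r2_definition``: "pearson" (squared correlation) or "explained"
    (1 - SSE/SST).
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length vectors")
    n = len(pred)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(pred).all() and np.isfinite(truth).all()):
        raise ValueError("inputs must be finite")
    diff = pred - truth
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    rmse = float(np.sqrt(np.mean(diff**2)))
    if pred.std() < 1e-15 or truth.std() < 1e-15:
        r = np.nan
    else:
        r = float(stats.pearsonr(pred, truth).statistic)
    if r2_definition == "pearson":
        r2 = r * r if np.isfinite(r) else np.nan
    elif r2_definition == "explained":
        sst = float(np.sum((truth - truth.mean()) ** 2))
        r2 = 1.0 - float(np.sum(diff**2)) / sst if sst > 0 else np.nan
    else:
        raise ValueError("r2_definition must be 'pearson' or 'explained'")
    if sd < 1e-15:
        p = 0.0 if abs(bias) > 1e-15 else 1.0
    else:
        p = float(stats.ttest_rel(pred, truth).pvalue)
    return AgreementReport(
        n=n,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        rmse=rmse,
        pearson_r=r,
        r_squared=r2,
        p_bias=p,
    )


def bland_altman_points(pred, truth) -> pd.DataFrame:
    """Plot payload: x = reference (truth), y = pred - truth, plus LoA lines."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    df = pd.DataFrame({"x": truth, "y": pred - truth})
    rep = agreement(pred, truth) if len(pred) >= 3 else None
    df.attrs["bias"] = rep.bias if rep else float((pred - truth).mean())
    df.attrs["loa_low"] = rep.loa_low if rep else np.nan
    df.attrs["loa_high"] = rep.loa_high if rep else np.nan
    return df


def change_analysis(phase1_pred, phase1_truth, phase2_pred, phase2_truth,
                    ids1=None, ids2=None) -> AgreementReport:
    """Agreement of predicted vs true within-subject change (phase2 - phase1)."""
    if ids1 is not None or ids2 is not None:
        ids1, ids2 = list(ids1), list(ids2)
        if ids1 != ids2:
            unmatched = sorted(set(ids1).symmetric_difference(ids2))
            raise ValueError(f"unmatched subject ids between phases: {unmatched[:10]}")
    p1p = np.asarray(phase1_pred, dtype=np.float64)
    p1t = np.asarray(phase1_truth, dtype=np.float64)
    p2p = np.asarray(phase2_pred, dtype=np.float64)
    p2t = np.asarray(phase2_truth, dtype=np.float64)
    return agreement(p2p - p1p, p2t - p1t)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def bland_altman_plot(pred, truth, *, ax=None, label: str = ""):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = bland_altman_points(pred, truth)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(df["x"], df["y"], s=6, alpha=0.5)
    for key, style in (("bias", "-"), ("loa_low", "--"), ("loa_high", "--")):
        ax.axhline(df.attrs[key], color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel(f"reference {label}")
    ax.set_ylabel("predicted - reference")
    return ax


def scatter_plot(pred, truth, *, ax=None, label: str = ""):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(truth, pred, s=6, alpha=0.5)
    lo = min(np.min(truth), np.min(pred))
    hi = max(np.max(truth), np.max(pred))
    ax.plot([lo, hi], [lo, hi], "k-", linewidth=0.8)
    ax.set_xlabel(f"reference {label}")
    ax.set_ylabel("predicted")
    return ax
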