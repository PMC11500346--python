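"""Product-of-Gaussians fusion of per-view body-shape estimates.

The smartphone pathway produces, for each photo, a diagonal Gaussian over the
shape coefficients.  Assuming conditional independence across views, the
posterior over shape given all views is proportional to the product of the
per-view Gaussians; for diagonal Gaussians this has the closed form

    precision_out = sum_n precision_n
    mean_out      = (sum_n mean_n * precision_n) / precision_out

computed per dimension.  The (unnormalized vs normalized) distinction does
not affect the returned mean/variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ShapeGaussian", "fuse_views"]


@dataclass
class ShapeGaussian:
    """Diagonal Gaussian over shape coefficients."""

    mean: np.ndarray  # (B,)
    variance: np.ndarray  # (B,), > 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.variance = np.asarray(self.variance, dtype=np.float64)
        if self.mean.shape != self.variance.shape:
            raise ValueError("mean and variance must have the same length")
        if np.any(self.variance <= 0):
            raise ValueError("variances must be positive")


def fuse_views(views: Sequence[ShapeGaussian]) -> ShapeGaussian:
    """Fuse per-view Gaussians into one shape estimate (order-invariant)."""
    if len(views) == 0:
        raise ValueError("need at least one view")
    b = views[0].mean.shape
    if any(v.mean.shape != b for v in views):
        raise ValueError("all views must share the same shape dimension")
    precision = np.zeros(b)
    weighted = np.zeros(b)
    for v in views:
        p = 1.0 / v.variance
        precision += p
        weighted += v.mean * p
    return ShapeGaussian(mean=weighted / precision, variance=1.0 / precision)
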