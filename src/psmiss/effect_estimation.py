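"""Stabilized IPW weights, percentile trimming, weighted effect, Rubin's rules.

The exposed are weighted by p_bar / p_i and the unexposed by
(1 - p_bar) / (1 - p_i), with p_bar the mean of the estimated propensity
scores.  Weights are trimmed by winsorization at the 1st and 99th
percentiles of the pooled weight distribution (row deletion is available
behind the `mode` switch).  The causal effect is the coefficient of T in a
weighted least-squares regression of Y on (1, T) with a model-based
standard error.  For multiply imputed data, per-imputation estimates are
combined by Rubin's rules: the point estimate is the mean, the total
variance is mean within-variance + (1 + 1/m) * between-variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EffectEstimate",
    "stabilized_weights",
    "trim_weights",
    "weighted_effect",
    "rubin_combine",
    "estimate_effect",
]


@dataclass
class EffectEstimate:
    """A point estimate of the exposure effect with its standard error."""

    estimate: float
    se: float
    n_effective: float = float("nan")
    method: str = ""
    strategy: str = ""
    per_imputation: list = field(default_factory=list)

    @property
    def variance(self) -> float:
        return self.se ** 2


def stabilized_weights(ps: np.ndarray, T: np.ndarray) -> np.ndarray:
    """w_i = p_bar / p_i for the exposed, (1 - p_bar)/(1 - p_i) otherwise."""
    ps = np.asarray(ps, dtype=float)
    if np.any(ps <= 0.0) or np.any(ps >= 1.0):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    p_bar = ps.mean()
    T = np.asarray(T)
    return np.where(T == 1, p_bar / ps, (1.0 - p_bar) / (1.0 - ps))


def trim_weights(
    w: np.ndarray,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    mode: str = "winsorize",
) -> np.ndarray:
    """Trim weights at distribution percentiles of the pooled weight vector.

    ``winsorize`` (default) truncates weights to the percentile values and
    drops no rows; ``drop`` zeroes the weight of rows outside the band,
    excluding them from the weighted regression.
    """
    w = np.asarray(w, dtype=float)
    # nearest-order-statistic percentiles make winsorization idempotent
    lo, hi = np.quantile(w, [lower_q, upper_q], method="nearest")
    if mode == "winsorize":
        return np.clip(w, lo, hi)
    if mode == "drop":
        out = w.copy()
        out[(w < lo) | (w > hi)] = 0.0
        return out
    raise ValueError(f"unknown trimming mode {mode!r}")


def weighted_effect(
    Y: np.ndarray, T: np.ndarray, w: np.ndarray, robust: bool = False
) -> EffectEstimate:
    """WLS of Y on (1, T); the estimate is the coefficient of T.

    The default standard error is the model-based WLS one
    (sigma^2 estimated from weighted residuals); ``robust`` switches to an
    HC0 sandwich.
    """
    Y = np.asarray(Y, dtype=float)
    T = np.asarray(T)
    w = np.asarray(w, dtype=float)
    t1 = T == 1
    sw1 = float(w[t1].sum())
    sw0 = float(w[~t1].sum())
    if sw1 <= 0.0 or sw0 <= 0.0:
        raise ValueError("each exposure class must carry positive total weight")
    m1 = float((w[t1] * Y[t1]).sum()) / sw1
    m0 = float((w[~t1] * Y[~t1]).sum()) / sw0
    est = m1 - m0
    resid = Y - np.where(t1, m1, m0)
    n = Y.shape[0]
    S = sw0 + sw1
    if robust:
        # sandwich: (X'WX)^-1 X'W diag(e^2) W X (X'WX)^-1, [T, T] element
        a = float((w[~t1] ** 2 * resid[~t1] ** 2).sum())
        b = float((w[t1] ** 2 * resid[t1] ** 2).sum())
        var = a / sw0 ** 2 + b / sw1 ** 2
    else:
        sigma2 = float((w * resid ** 2).sum()) / (n - 2)
        var = sigma2 * S / (sw1 * sw0)
    n_eff = S ** 2 / float((w ** 2).sum())
    return EffectEstimate(estimate=est, se=float(np.sqrt(var)), n_effective=n_eff)


def rubin_combine(estimates, variances, method: str = "", strategy: str = "") -> EffectEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates to combine")
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")
    m = est.size
    point = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1)) if m > 1 else 0.0
    total = within + (1.0 + 1.0 / m) * between
    return EffectEstimate(
        estimate=point,
        se=float(np.sqrt(total)),
        method=method,
        strategy=strategy,
        per_imputation=list(zip(est.tolist(), var.tolist())),
    )


def estimate_effect(
    Y: np.ndarray,
    T: np.ndarray,
    ps: np.ndarray,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    mode: str = "winsorize",
    robust: bool = False,
) -> EffectEstimate:
    """Convenience pipeline: stabilize, trim, weighted regression."""
    w = stabilized_weights(ps, T)
    w = trim_weights(w, lower_q, upper_q, mode=mode)
    return weighted_effect(Y, T, w, robust=robust)
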