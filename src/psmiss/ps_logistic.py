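"""Logistic-regression propensity scores under variable-inclusion strategies.

Strategies for the main-effects logistic model: the true confounders
x1..x4, leaving x1 out, adding the non-confounder x5, or both; a fifth
strategy ("correct_G") uses the full scenario-G specification (x1..x7 plus
its 3 quadratic and 10 interaction terms).  A pooled missingness-pattern
indicator, when supplied, enters the design as dummies with the largest
group as reference.

Fitting is maximum likelihood by iteratively reweighted least squares
(deviance tolerance 1e-8, at most 100 iterations); fitted probabilities
are clipped to [1e-6, 1 - 1e-6] so downstream inverse-probability weights
stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .synthetic_data import EXPOSURE_INTERACTIONS, EXPOSURE_QUADRATIC

__all__ = [
    "STRATEGIES",
    "PropensityFit",
    "build_design",
    "fit_logistic_ps",
    "PerfectSeparationError",
    "ConvergenceError",
]

logger = logging.getLogger(__name__)

#: Main-effect columns (0-based) per inclusion strategy.
STRATEGIES = {
    "true_confounders": (0, 1, 2, 3),
    "leave_x1_out": (1, 2, 3),
    "add_x5": (0, 1, 2, 3, 4),
    "leave_x1_out_add_x5": (1, 2, 3, 4),
    "correct_G": (0, 1, 2, 3, 4, 5, 6),
}

PS_CLIP = 1e-6


class PerfectSeparationError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PropensityFit:
    """Estimated propensity scores with their provenance."""

    ps: np.ndarray
    coefficients: np.ndarray
    strategy: str
    estimator: str = "logistic"
    converged: bool = True


def build_design(
    X: np.ndarray,
    strategy: str,
    pattern_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Intercept + strategy terms (+ pattern dummies) as a design matrix.

    "correct_G" appends the quadratic and interaction terms of the
    scenario-G generator (21 columns in total).  Pattern dummies use the
    largest pooled group as reference; constant columns are dropped.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown inclusion strategy {strategy!r}")
    cols = STRATEGIES[strategy]
    if X.shape[1] <= max(cols):
        raise ValueError(f"design requires column index {max(cols)}, X has {X.shape[1]}")
    parts = [np.ones((X.shape[0], 1)), X[:, cols]]
    if strategy == "correct_G":
        quads = np.column_stack([X[:, j] ** 2 for j in EXPOSURE_QUADRATIC])
        inters = np.column_stack(
            [X[:, i] * X[:, j] for (i, j) in EXPOSURE_INTERACTIONS]
        )
        parts += [quads, inters]
    if pattern_ids is not None:
        uniq, counts = np.unique(pattern_ids, return_counts=True)
        # reference = largest group (ties -> lowest id)
        ref = uniq[np.argmax(counts)]
        for g in uniq:
            if g == ref:
                continue
            parts.append((pattern_ids == g).astype(float)[:, None])
    D = np.hstack(parts)
    keep = np.ptp(D, axis=0) > 0
    keep[0] = True  # intercept
    return D[:, keep]


def fit_logistic_ps(
    design: np.ndarray,
    T: np.ndarray,
    strategy: str = "",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PropensityFit:
    """Maximum-likelihood logistic fit by IRLS.

    Raises
    ------
    ValueError
        If T does not contain both classes.
    PerfectSeparationError
        If the likelihood diverges (fitted probabilities degenerate).
    ConvergenceError
        If the deviance has not stabilized after `max_iter` iterations.
    """
    T = np.asarray(T, dtype=float)
    if T.min() == T.max():
        raise ValueError("exposure vector must contain both classes")
    n, p = design.shape
    beta = np.zeros(p)
    eta = design @ beta
    dev_old = np.inf
    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1.0 - mu)
        z = eta + (T - mu) / w
        WD = design * w[:, None]
        try:
            beta = np.linalg.solve(design.T @ WD, WD.T @ z)
        except np.linalg.LinAlgError:
            raise PerfectSeparationError(
                "singular weighted design; inspect the data for separation "
                "or collinearity"
            ) from None
        eta = design @ beta
        mu_new = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        dev = -2.0 * float(T @ np.log(mu_new) + (1.0 - T) @ np.log(1.0 - mu_new))
        if np.abs(eta).max() > 30.0 and dev < 1e-6:
            raise PerfectSeparationError(
                "perfect separation detected (fitted probabilities at 0/1); "
                "inspect the covariates"
            )
        if abs(dev - dev_old) < tol:
            converged = True
            break
        dev_old = dev
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    ps = expit(eta)
    n_clip = int((ps < PS_CLIP).sum() + (ps > 1 - PS_CLIP).sum())
    if n_clip:
        logger.debug("clipping %d fitted propensity scores to [%g, %g]", n_clip, PS_CLIP, 1 - PS_CLIP)
    ps = np.clip(ps, PS_CLIP, 1 - PS_CLIP)
    return PropensityFit(ps=ps, coefficients=beta, strategy=strategy, converged=converged)
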