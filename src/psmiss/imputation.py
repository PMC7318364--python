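"""Imputation strategies for missing confounders.

Five strategies produce completed covariate matrices:

* treatment-mean imputation (TMI) — missing cells replaced by the unrounded
  mean of observed values within the subject's exposure group;
* single imputation with prediction error (SI+PE) — one pass of the
  chained-equations engine, imputing each incomplete variable from a linear
  model plus a residual-scale noise draw, coefficients treated as fixed;
* SI+PE+PU — as SI+PE but each refit first draws (sigma^2, beta) from the
  standard noninformative conjugate posterior;
* chained-equations multiple imputation (MI) — m independent completed
  datasets, each from a fresh random initialization followed by
  `n_cycles` sweeps of per-variable refits (fully conditional
  specification); the default per-variable draw is predictive mean
  matching, with a Bayesian normal model selectable;
* MIMP — MI plus a pooled missingness-pattern indicator for inclusion in
  the propensity model.

The imputation models use x1..x6, x8, x9, T and Y (x7 and x10 excluded as
uncorrelated with the incomplete variables).  Binary targets are imputed on
the continuous scale and never rounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg.lapack import dpotrf, dpotrs, dtrtrs

from .missingness import CONFOUNDER_COLUMNS, IncompleteSample

__all__ = [
    "ImputationOutput",
    "PatternPooling",
    "treatment_mean_impute",
    "regression_impute_pe",
    "regression_impute_pe_pu",
    "chained_equations_impute",
    "pool_patterns",
    "mimp_impute",
    "IMPUTER_COVARIATE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Covariate columns entering every imputation model (x7 and x10 excluded).
IMPUTER_COVARIATE_COLUMNS = (0, 1, 2, 3, 4, 5, 7, 8)


class ImputationError(RuntimeError):
    pass


@dataclass
class ImputationOutput:
    """m completed covariate matrices plus optional pattern labels."""

    completed: list
    method: str
    pattern_ids: np.ndarray | None = None
    imputer_columns: tuple = IMPUTER_COVARIATE_COLUMNS

    @property
    def m(self) -> int:
        return len(self.completed)

    def to_frame(self):
        """Stack completed datasets with an imputation-index column."""
        import pandas as pd

        from .synthetic_data import COLUMN_NAMES

        frames = []
        for i, X in enumerate(self.completed):
            df = pd.DataFrame(X, columns=list(COLUMN_NAMES))
            df.insert(0, "imputation", i + 1)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def treatment_mean_impute(sample: IncompleteSample) -> ImputationOutput:
    """Replace missing cells with the exposure-group mean of observed values."""
    X = sample.base.X.copy()
    T = sample.base.T
    for j, col in enumerate(CONFOUNDER_COLUMNS):
        mis = sample.mask[:, j]
        if not mis.any():
            continue
        for t in (0, 1):
            grp = (T == t) & mis
            if not grp.any():
                continue
            obs = (T == t) & ~mis
            if not obs.any():
                raise ImputationError(
                    f"no observed values of x{col + 1} in exposure group T={t}"
                )
            X[grp, col] = sample.base.X[obs, col].mean()
    return ImputationOutput(completed=[X], method="TMI")


def _fit_linear(D: np.ndarray, y: np.ndarray, rng: np.random.Generator, posterior_draw: bool):
    """Least-squares fit of y on D; returns (beta, noise SD).

    With ``posterior_draw`` the parameters are drawn from the standard
    noninformative conjugate posterior: sigma^2 ~ SSE / chi2(n - p),
    beta | sigma^2 ~ N(beta_hat, sigma^2 (D'D)^-1).  Rank-deficient
    designs fall back to a pseudoinverse fit with a logged warning.
    """
    n, p = D.shape
    DtD = D.T @ D
    Dty = D.T @ y
    # Cholesky DtD = L L'; solve for beta, and reuse L for the beta draw
    L, info = dpotrf(DtD, lower=1, overwrite_a=False)
    if info == 0:
        beta, _ = dpotrs(L, Dty, lower=1)
        chol_ok = True
    else:
        logger.warning("rank-deficient imputation design; using pseudoinverse")
        beta = np.linalg.pinv(D) @ y
        chol_ok = False
    resid = y - D @ beta
    dof = max(n - p, 1)
    sse = float(resid @ resid)
    if not posterior_draw:
        return beta, np.sqrt(sse / dof)
    sigma2 = sse / rng.chisquare(dof)
    if chol_ok:
        # chol factor of (D'D)^-1 is L^-T, so beta_draw = beta + s * L^-T z
        z = rng.standard_normal(p)
        step, _ = dtrtrs(L, z, lower=1, trans=1)
        beta = beta + np.sqrt(sigma2) * step
    else:
        cov = np.linalg.pinv(DtD)
        beta = rng.multivariate_normal(beta, sigma2 * cov, method="svd")
    return beta, np.sqrt(sigma2)


def _pmm_draw(D_obs, y_obs, D_mis, rng, n_donors=5):
    """Predictive-mean-matching draw for the missing cells.

    Predictions for the observed cases use the least-squares fit and those
    for the missing cases a posterior parameter draw (type-1 matching);
    each missing cell receives the observed value of one of the
    `n_donors` donors closest in predicted value, chosen at random.
    """
    n, p = D_obs.shape
    DtD = D_obs.T @ D_obs
    Dty = D_obs.T @ y_obs
    L, info = dpotrf(DtD, lower=1)
    if info != 0:
        logger.warning("rank-deficient imputation design; using pseudoinverse")
        beta_hat = np.linalg.pinv(D_obs) @ y_obs
        beta_star = beta_hat
    else:
        beta_hat, _ = dpotrs(L, Dty, lower=1)
        resid = y_obs - D_obs @ beta_hat
        dof = max(n - p, 1)
        sigma2 = float(resid @ resid) / rng.chisquare(dof)
        z = rng.standard_normal(p)
        step, _ = dtrtrs(L, z, lower=1, trans=1)
        beta_star = beta_hat + np.sqrt(sigma2) * step
    yhat_obs = D_obs @ beta_hat
    yhat_mis = D_mis @ beta_star
    order = np.argsort(yhat_obs, kind="stable")
    yo = yhat_obs[order]
    pos = np.searchsorted(yo, yhat_mis)
    # the n_donors nearest predicted values lie inside a +-n_donors window
    offs = np.arange(-n_donors, n_donors)
    cand = np.clip(pos[:, None] + offs, 0, n - 1)
    dist = np.abs(yo[cand] - yhat_mis[:, None])
    nearest = np.argpartition(dist, n_donors - 1, axis=1)[:, :n_donors]
    pick = rng.integers(0, n_donors, size=yhat_mis.size)
    donor_sorted_idx = np.take_along_axis(cand, nearest, axis=1)[
        np.arange(yhat_mis.size), pick
    ]
    return y_obs[order[donor_sorted_idx]]


def _chained_pass(
    sample: IncompleteSample,
    rng: np.random.Generator,
    n_cycles: int,
    model: str,
) -> np.ndarray:
    """One chained-equations run: initialize, sweep, return a completed matrix.

    ``model``: "norm_nob" (prediction + residual noise, fixed parameters),
    "norm" (posterior parameter draw first), or "pmm" (predictive mean
    matching with 5 donors).
    """
    if model not in ("norm", "norm_nob", "pmm"):
        raise ValueError(f"unknown imputation model {model!r}")
    X0 = sample.base.X
    T = sample.base.T.astype(float)
    Y = sample.base.Y
    Xc = X0.copy()
    incomplete = [
        (j, col) for j, col in enumerate(CONFOUNDER_COLUMNS) if sample.mask[:, j].any()
    ]
    # initialize missing cells from the observed margin of each variable
    for j, col in incomplete:
        mis = sample.mask[:, j]
        obs_vals = X0[~mis, col]
        if obs_vals.size == 0:
            raise ImputationError(f"x{col + 1} has no observed values")
        Xc[mis, col] = rng.choice(obs_vals, size=int(mis.sum()), replace=True)
    ones = np.ones(sample.n)
    for _ in range(n_cycles):
        for j, col in incomplete:
            mis = sample.mask[:, j]
            preds = [c for c in IMPUTER_COVARIATE_COLUMNS if c != col]
            D = np.column_stack([ones, Xc[:, preds], T, Y])
            if model == "pmm":
                Xc[mis, col] = _pmm_draw(D[~mis], X0[~mis, col], D[mis], rng)
            else:
                beta, sigma = _fit_linear(
                    D[~mis], X0[~mis, col], rng, posterior_draw=(model == "norm")
                )
                Xc[mis, col] = D[mis] @ beta + sigma * rng.standard_normal(
                    int(mis.sum())
                )
    return Xc


def regression_impute_pe(
    sample: IncompleteSample, rng=None, n_cycles: int = 10
) -> ImputationOutput:
    """Single imputation with prediction error (no parameter draw)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Xc = _chained_pass(sample, rng, n_cycles, model="norm_nob")
    return ImputationOutput(completed=[Xc], method="SI_PE")


def regression_impute_pe_pu(
    sample: IncompleteSample, rng=None, n_cycles: int = 10
) -> ImputationOutput:
    """Single imputation with prediction error and parameter uncertainty."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Xc = _chained_pass(sample, rng, n_cycles, model="norm")
    return ImputationOutput(completed=[Xc], method="SI_PE_PU")


def chained_equations_impute(
    sample: IncompleteSample,
    m: int = 20,
    n_cycles: int = 10,
    rng=None,
    model: str = "pmm",
) -> ImputationOutput:
    """Fully-conditional-specification multiple imputation (m datasets).

    The default per-variable model is predictive mean matching (the
    reference chained-equations software's default for numeric data),
    which preserves non-linear covariate relations; a Bayesian normal
    model is available via ``model="norm"``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    completed = [_chained_pass(sample, rng, n_cycles, model) for _ in range(m)]
    return ImputationOutput(completed=completed, method="MI")


@dataclass
class PatternPooling:
    """Per-subject pooled missingness-pattern labels."""

    ids: np.ndarray
    #: pooled group id -> (set of 4-bit signatures, subject count)
    groups: dict = field(default_factory=dict)


def _hamming(a: int, b: int) -> int:
    return bin(a ^ b).count("1")


def pool_patterns(mask: np.ndarray, min_count: int = 100) -> PatternPooling:
    """Pool rare missingness patterns until every group reaches `min_count`.

    Patterns are the 4-bit signatures of (x1..x4 missing).  While any group
    is smaller than `min_count` and more than one group remains, the
    smallest group is merged into the group at minimum Hamming distance
    (distance between groups = minimum over their signature pairs; ties
    resolved toward the larger group, then the lower group index).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    sigs = (mask.astype(int) * np.array([8, 4, 2, 1])).sum(axis=1)
    uniq, counts = np.unique(sigs, return_counts=True)
    groups = [[{int(s)}, int(c)] for s, c in zip(uniq, counts)]
    while len(groups) > 1 and min(g[1] for g in groups) < min_count:
        gi = min(range(len(groups)), key=lambda i: (groups[i][1], i))
        best = None
        for i, (sset, cnt) in enumerate(groups):
            if i == gi:
                continue
            d = min(_hamming(a, b) for a in groups[gi][0] for b in sset)
            key = (d, -cnt, i)
            if best is None or key < best[0]:
                best = (key, i)
        ti = best[1]
        groups[ti][0] |= groups[gi][0]
        groups[ti][1] += groups[gi][1]
        del groups[gi]
    sig_to_id = {}
    info = {}
    for gid, (sset, cnt) in enumerate(groups):
        info[gid] = (frozenset(sset), cnt)
        for s in sset:
            sig_to_id[s] = gid
    ids = np.array([sig_to_id[int(s)] for s in sigs], dtype=np.int64)
    return PatternPooling(ids=ids, groups=info)


def mimp_impute(
    sample: IncompleteSample,
    m: int = 20,
    min_count: int = 100,
    n_cycles: int = 10,
    rng=None,
    model: str = "pmm",
) -> ImputationOutput:
    """MI plus a pooled missingness-pattern indicator.

    The indicator depends only on the mask and is therefore identical
    across the m imputations; downstream it enters the propensity model as
    categorical dummies.
    """
    out = chained_equations_impute(sample, m=m, n_cycles=n_cycles, rng=rng, model=model)
    pooling = pool_patterns(sample.mask, min_count=min_count)
    return ImputationOutput(
        completed=out.completed, method="MIMP", pattern_ids=pooling.ids
    )
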