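"""Missingness mechanisms on the four true confounders x1..x4.

All mechanisms leave x5..x10, T and Y fully observed and act cell-wise and
independently (Bernoulli missingness) on x1..x4:

* MCAR — each cell missing with the overall rate, independently of
  everything.
* MAR-1 — missingness on x1..x4 driven by x5, x6, x8, x9 respectively,
  with conditional rates 15%/35% (overall ~25%) or 30%/70% (overall ~50%)
  depending on the driver's value.  For Bernoulli(0.3) drivers the marginal
  rate is 21% / 42%, not 25% / 50%; the conditional rates are taken as
  authoritative and no rescaling is applied.
* MAR-2 — observations grouped by (driver value, 1{Y > mean(Y)}) with
  group-specific rates whose weighted sum matches the overall rate.
* MAR-sinister — observations are randomly split into 20 groups; within
  each group the correlation between a driver covariate and T (or Y) is
  computed; the 10 lower-correlation groups receive the low rate and the
  10 higher ones the high rate (10%/40% overall 25%, 30%/70% overall 50%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic_data import CompleteSample

__all__ = [
    "IncompleteSample",
    "impose_mcar",
    "impose_mar1",
    "impose_mar2",
    "impose_mar_sinister",
    "impose",
    "MAR2_TABLES",
    "MAR1_CONDITIONAL_RATES",
    "SINISTER_RATES",
]

logger = logging.getLogger(__name__)

#: 0-based columns of the incomplete covariates x1..x4.
CONFOUNDER_COLUMNS = (0, 1, 2, 3)

#: Drivers of MAR-1 and MAR-2 missingness on x1..x4: x5, x6, x8, x9.
MAR_DRIVER_COLUMNS = (4, 5, 7, 8)

#: MAR-1 conditional rates (driver = 0, driver = 1) by overall rate.
MAR1_CONDITIONAL_RATES = {0.25: (0.15, 0.35), 0.50: (0.30, 0.70)}

#: MAR-2 group rates by overall rate, per target covariate x1..x4.
#: Groups are ordered (driver=0, Y<=mean), (0, >), (1, <=), (1, >).
MAR2_TABLES = {
    0.25: {
        0: (0.10, 0.20, 0.30, 0.40),
        1: (0.25, 0.30, 0.20, 0.15),
        2: (0.30, 0.25, 0.15, 0.20),
        3: (0.15, 0.25, 0.35, 0.20),
    },
    0.50: {
        0: (0.20, 0.40, 0.60, 0.80),
        1: (0.50, 0.60, 0.40, 0.30),
        2: (0.60, 0.50, 0.30, 0.40),
        3: (0.30, 0.50, 0.70, 0.40),
    },
}

#: MAR-sinister (low-half, high-half) group rates by overall rate.
SINISTER_RATES = {0.25: (0.10, 0.40), 0.50: (0.30, 0.70)}

#: Default MAR-sinister (driver column, partner) pairs for x1..x4; the
#: partner is the exposure T or the outcome Y.
SINISTER_DRIVERS = ((4, "T"), (5, "T"), (7, "Y"), (8, "Y"))

#: Alternative literal pairing using x7 and x8 for the outcome-side drivers.
SINISTER_DRIVERS_LITERAL = ((4, "T"), (5, "T"), (6, "Y"), (7, "Y"))


@dataclass
class IncompleteSample:
    """A complete sample with a missingness mask on x1..x4 (True = missing)."""

    base: CompleteSample
    mask: np.ndarray
    mechanism: str

    @property
    def n(self) -> int:
        return self.base.n

    def masked_covariates(self) -> np.ndarray:
        """Covariate matrix with masked cells replaced by NaN."""
        X = self.base.X.copy()
        for j, col in enumerate(CONFOUNDER_COLUMNS):
            X[self.mask[:, j], col] = np.nan
        return X

    def to_frame(self):
        df = self.base.to_frame()
        for j in range(4):
            df[f"m{j + 1}"] = self.mask[:, j].astype(int)
        return df


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def impose_mcar(sample: CompleteSample, rate: float, rng=None) -> IncompleteSample:
    """Each cell of x1..x4 missing independently with probability `rate`."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = _as_rng(rng)
    mask = rng.random((sample.n, 4)) < rate
    return IncompleteSample(base=sample, mask=mask, mechanism="MCAR")


def impose_mar1(
    sample: CompleteSample,
    overall_rate: float,
    rng=None,
    conditional_rates: tuple[float, float] | None = None,
) -> IncompleteSample:
    """Missingness on x1..x4 at conditional rates given x5, x6, x8, x9."""
    if conditional_rates is None:
        conditional_rates = MAR1_CONDITIONAL_RATES[overall_rate]
    r0, r1 = conditional_rates
    rng = _as_rng(rng)
    mask = np.zeros((sample.n, 4), dtype=bool)
    u = rng.random((sample.n, 4))
    for j, driver in enumerate(MAR_DRIVER_COLUMNS):
        p = np.where(sample.X[:, driver] == 1, r1, r0)
        mask[:, j] = u[:, j] < p
    return IncompleteSample(base=sample, mask=mask, mechanism="MAR1")


def impose_mar2(
    sample: CompleteSample,
    overall_rate: float,
    rng=None,
    tables: dict | None = None,
) -> IncompleteSample:
    """Group-specific missingness by (driver value, indicator Y > mean(Y)).

    The Y split uses the realized sample mean of Y, recomputed per call.
    """
    if tables is None:
        tables = MAR2_TABLES[overall_rate]
    rng = _as_rng(rng)
    above = (sample.Y > sample.Y.mean()).astype(int)
    mask = np.zeros((sample.n, 4), dtype=bool)
    u = rng.random((sample.n, 4))
    for j, driver in enumerate(MAR_DRIVER_COLUMNS):
        if j not in tables:
            raise KeyError(f"MAR-2 table missing for target covariate x{j + 1}")
        rates = tables[j]
        group = 2 * (sample.X[:, driver] == 1).astype(int) + above
        p = np.asarray(rates)[group]
        mask[:, j] = u[:, j] < p
    return IncompleteSample(base=sample, mask=mask, mechanism="MAR2")


def impose_mar_sinister(
    sample: CompleteSample,
    overall_rate: float,
    rng=None,
    rates: tuple[float, float] | None = None,
    drivers: tuple = SINISTER_DRIVERS,
    n_groups: int = 20,
) -> IncompleteSample:
    """Missingness driven by group-level correlation with T or Y.

    Observations are randomly partitioned into `n_groups` near-equal
    groups (one partition shared by the four targets).  For each target
    covariate the Pearson correlation of its (driver, partner) pair is
    computed within each group; the lower half of groups (stable sort by
    correlation, ties broken by group index) receives the low rate, the
    upper half the high rate.  Groups with zero variance in either member
    are ranked with correlation 0.
    """
    if rates is None:
        rates = SINISTER_RATES[overall_rate]
    low, high = rates
    rng = _as_rng(rng)
    n = sample.n
    if n < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} observations, got {n}")
    perm = rng.permutation(n)
    groups = np.array_split(perm, n_groups)
    mask = np.zeros((n, 4), dtype=bool)
    u = rng.random((n, 4))
    for j, (driver, partner) in enumerate(drivers):
        corrs = np.empty(n_groups)
        for g, rows in enumerate(groups):
            a = sample.X[rows, driver]
            b = sample.T[rows] if partner == "T" else sample.Y[rows]
            if np.std(a) == 0.0 or np.std(b) == 0.0:
                logger.debug(
                    "zero variance in group %d for target x%d; correlation set to 0",
                    g, j + 1,
                )
                corrs[g] = 0.0
            else:
                corrs[g] = np.corrcoef(a, b)[0, 1]
        order = np.argsort(corrs, kind="stable")
        p = np.empty(n)
        for rank, g in enumerate(order):
            p[groups[g]] = low if rank < n_groups // 2 else high
        mask[:, j] = u[:, j] < p
    return IncompleteSample(base=sample, mask=mask, mechanism="MARSINISTER")


_MECHANISMS = {
    "MCAR": impose_mcar,
    "MAR1": impose_mar1,
    "MAR2": impose_mar2,
    "MARSINISTER": impose_mar_sinister,
}


def impose(sample: CompleteSample, mechanism: str, overall_rate: float, rng=None, **kwargs) -> IncompleteSample:
    """Dispatch to a mechanism by name (MCAR, MAR1, MAR2, MARSINISTER)."""
    try:
        fn = _MECHANISMS[mechanism.upper()]
    except KeyError:
        raise ValueError(f"unknown missingness mechanism {mechanism!r}") from None
    return fn(sample, overall_rate, rng, **kwargs)
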