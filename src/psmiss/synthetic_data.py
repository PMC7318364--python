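"""Complete-data generator for the propensity-score missingness study.

Ten covariates x1..x10 are drawn from a latent 10-dimensional standard
normal with four correlated pairs; six coordinates are dichotomized at the
normal quantile matching their Bernoulli success probability (0.3 for x1,
x6, x8 and 0.5 for x3, x5, x9), the other four are kept as N(0, 1).
A binary exposure T follows a logistic model in x1..x7 — scenario A uses
main effects only, scenario G adds three quadratic and ten two-way
interaction terms — and a continuous outcome Y is linear in x1..x4, x8..x10
and T with a true exposure effect of -0.4 and unit-variance normal noise.
x1..x4 affect both T and Y and are therefore the true confounders.

Correlations are specified on the *latent* normal scale: a Pearson
correlation of 0.9 between a Bernoulli(0.3) and an N(0,1) variable is
unattainable (the point-biserial maximum is ~0.76), so the stated rho
values are imposed on the underlying multivariate normal before
dichotomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "GeneratorConfig",
    "ExposureModel",
    "CompleteSample",
    "generate_covariates",
    "assign_exposure",
    "generate_outcome",
    "generate_complete_sample",
    "write_fixture",
    "TRUE_EFFECT",
    "DEFAULT_CORR_PAIRS",
    "LITERAL_CORR_PAIRS",
    "DEFAULT_BINARY_PROBS",
]

N_COVARIATES = 10

#: 0-based column indices of the binary covariates (x1, x3, x5, x6, x8, x9).
BINARY_COLUMNS = (0, 2, 4, 5, 7, 8)

#: Marginal success probabilities of the binary covariates.
DEFAULT_BINARY_PROBS = {0: 0.3, 2: 0.5, 4: 0.5, 5: 0.3, 7: 0.3, 8: 0.5}

#: Latent-scale correlation pairs (i, j, rho), 0-based.  Default pairing:
#: x1-x5 (0.2), x2-x6 (0.9), x3-x8 (0.2), x4-x9 (0.9) — x8 and x9 are the
#: outcome-side auxiliaries correlated with confounders x3 and x4.
DEFAULT_CORR_PAIRS = ((0, 4, 0.2), (1, 5, 0.9), (2, 7, 0.2), (3, 8, 0.9))

#: Alternative pairing with x3-x7 (0.2) and x4-x8 (0.9).
LITERAL_CORR_PAIRS = ((0, 4, 0.2), (1, 5, 0.9), (2, 6, 0.2), (3, 7, 0.9))

#: Main-effect coefficients on x1..x7 of the exposure logit (both scenarios).
EXPOSURE_MAIN = (0.8, -0.25, 0.6, -0.4, -0.8, -0.5, 0.7)

#: Scenario-G quadratic terms: column index -> coefficient (x2^2, x4^2, x7^2).
EXPOSURE_QUADRATIC = {1: -0.25, 3: -0.4, 6: 0.7}

#: Scenario-G two-way interactions: (i, j) -> coefficient (0-based columns).
EXPOSURE_INTERACTIONS = {
    (0, 2): 0.4,
    (1, 3): -0.175,
    (2, 4): 0.3,
    (3, 5): -0.28,
    (4, 6): -0.4,
    (0, 5): 0.4,
    (1, 2): -0.175,
    (2, 3): 0.3,
    (3, 4): -0.2,
    (4, 5): -0.4,
}

OUTCOME_INTERCEPT = -3.85
#: Outcome coefficients: column index -> coefficient.
OUTCOME_COEF = {0: 0.3, 1: -0.36, 2: -0.73, 3: -0.2, 7: 0.71, 8: -0.19, 9: 0.26}
TRUE_EFFECT = -0.4

COLUMN_NAMES = tuple(f"x{i + 1}" for i in range(N_COVARIATES))


class ConfigurationError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one complete-data draw.

    Parameters
    ----------
    n : int
        Sample size (the study uses 500, 1000 and 5000).
    scenario : {"A", "G"}
        Exposure model: main effects only (A) or with moderate
        non-additivity and non-linearity (G).
    seed : int or None
        Seed for the generator when no external RNG is supplied.
    latent_corr_pairs : tuple of (i, j, rho)
        Pairwise correlations on the latent normal scale, 0-based columns.
    binary_probs : dict
        Column index -> Bernoulli success probability for binary columns.
    """

    n: int
    scenario: str = "A"
    seed: int | None = None
    latent_corr_pairs: tuple = DEFAULT_CORR_PAIRS
    binary_probs: dict = field(default_factory=lambda: dict(DEFAULT_BINARY_PROBS))

    def __post_init__(self):
        if self.n < 0:
            raise ConfigurationError(f"sample size must be non-negative, got {self.n}")
        if self.scenario not in ("A", "G"):
            raise ConfigurationError(f"scenario must be 'A' or 'G', got {self.scenario!r}")

    def latent_correlation(self) -> np.ndarray:
        """Assemble and validate the 10x10 latent correlation matrix."""
        R = np.eye(N_COVARIATES)
        for i, j, rho in self.latent_corr_pairs:
            R[i, j] = R[j, i] = rho
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ConfigurationError(
                "latent correlation matrix is not positive definite"
            ) from None
        return R


@dataclass(frozen=True)
class ExposureModel:
    """Coefficients of the true exposure logit for one scenario."""

    scenario: str
    main: tuple = EXPOSURE_MAIN
    quadratic: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)
    intercept: float = 0.0

    @classmethod
    def from_scenario(cls, scenario: str) -> "ExposureModel":
        if scenario == "A":
            return cls(scenario="A")
        if scenario == "G":
            return cls(
                scenario="G",
                quadratic=dict(EXPOSURE_QUADRATIC),
                interactions=dict(EXPOSURE_INTERACTIONS),
            )
        raise ConfigurationError(f"unknown scenario {scenario!r}")

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        lp = np.full(X.shape[0], self.intercept)
        for j, b in enumerate(self.main):
            lp += b * X[:, j]
        for j, b in self.quadratic.items():
            lp += b * X[:, j] ** 2
        for (i, j), b in self.interactions.items():
            lp += b * X[:, i] * X[:, j]
        return lp


@dataclass
class CompleteSample:
    """A generated complete dataset with its generating truths."""

    X: np.ndarray
    T: np.ndarray
    Y: np.ndarray
    true_ps: np.ndarray
    scenario: str
    true_effect: float = TRUE_EFFECT

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=list(COLUMN_NAMES))
        df["T"] = self.T
        df["Y"] = self.Y
        return df


def generate_covariates(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the n x 10 covariate matrix.

    Continuous columns are marginally N(0, 1); binary columns are obtained
    by thresholding the latent normal at the quantile that yields the
    configured success probability, which preserves the latent pairwise
    correlations.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    R = cfg.latent_correlation()
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((cfg.n, N_COVARIATES)) @ L.T
    X = Z
    for j, p in cfg.binary_probs.items():
        X[:, j] = (Z[:, j] > norm.ppf(1.0 - p)).astype(float)
    return X


def assign_exposure(
    X: np.ndarray,
    model: ExposureModel | str,
    rng: np.random.Generator | None = None,
    uniforms: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw exposure T ~ Bernoulli(true_ps) under the scenario logit.

    `uniforms` is a test hook: when given, T = 1{u < true_ps} instead of a
    fresh random draw.
    """
    if X.shape[1] != N_COVARIATES:
        raise ValueError(f"expected {N_COVARIATES} covariate columns, got {X.shape[1]}")
    if isinstance(model, str):
        model = ExposureModel.from_scenario(model)
    true_ps = expit(model.linear_predictor(X))
    if uniforms is None:
        if rng is None:
            rng = np.random.default_rng()
        uniforms = rng.random(X.shape[0])
    T = (uniforms < true_ps).astype(np.int64)
    return T, true_ps


def generate_outcome(
    X: np.ndarray,
    T: np.ndarray,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | float | None = None,
) -> np.ndarray:
    """Continuous outcome, linear in the confounders and T with N(0,1) noise.

    `noise` is a test hook overriding the random error (e.g. 0 to suppress).
    """
    Y = np.full(X.shape[0], OUTCOME_INTERCEPT)
    for j, b in OUTCOME_COEF.items():
        Y += b * X[:, j]
    Y += TRUE_EFFECT * np.asarray(T, dtype=float)
    if noise is None:
        if rng is None:
            rng = np.random.default_rng()
        noise = rng.standard_normal(X.shape[0])
    return Y + noise


def generate_complete_sample(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> CompleteSample:
    """One end-to-end draw: covariates, exposure, outcome."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    X = generate_covariates(cfg, rng)
    T, true_ps = assign_exposure(X, cfg.scenario, rng)
    Y = generate_outcome(X, T, rng)
    return CompleteSample(X=X, T=T, Y=Y, true_ps=true_ps, scenario=cfg.scenario)


def write_fixture(sample: CompleteSample, path, sep: str = "\t") -> None:
    """Write a sample as a delimited table with header x1..x10,T,Y."""
    sample.to_frame().to_csv(path, sep=sep, index=False)
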