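"""Imputation engines: observed-cell preservation, noise models, pooling."""

import numpy as np
import pytest

from psmiss.imputation import (
    ImputationError,
    chained_equations_impute,
    mimp_impute,
    pool_patterns,
    regression_impute_pe,
    regression_impute_pe_pu,
    treatment_mean_impute,
)
from psmiss.missingness import IncompleteSample, impose_mcar
from psmiss.synthetic_data import CompleteSample, GeneratorConfig, generate_complete_sample


def _make_incomplete(X, T, mask, Y=None):
    n = X.shape[0]
    base = CompleteSample(
        X=np.asarray(X, dtype=float),
        T=np.asarray(T),
        Y=np.zeros(n) if Y is None else np.asarray(Y, dtype=float),
        true_ps=np.full(n, 0.5),
        scenario="A",
    )
    return IncompleteSample(base=base, mask=np.asarray(mask, dtype=bool), mechanism="manual")


def test_treatment_mean_imputation_hand_example():
    # T=1 group observes x1 values {0, 1, 1} -> missing cells get 2/3
    X = np.zeros((8, 10))
    X[:, 0] = [0, 1, 1, 0, 0, 0, 1, 0]
    T = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    mask = np.zeros((8, 4), dtype=bool)
    mask[3, 0] = True   # T=1 missing
    mask[7, 0] = True   # T=0 missing
    out = treatment_mean_impute(_make_incomplete(X, T, mask))
    Xc = out.completed[0]
    assert Xc[3, 0] == pytest.approx(2 / 3)          # unrounded group mean
    assert Xc[7, 0] == pytest.approx(1 / 3)
    assert out.m == 1


def test_treatment_mean_identity_without_missingness(sample_a):
    inc = IncompleteSample(base=sample_a, mask=np.zeros((sample_a.n, 4), bool), mechanism="none")
    out = treatment_mean_impute(inc)
    np.testing.assert_array_equal(out.completed[0], sample_a.X)


def test_treatment_mean_error_when_group_unobserved():
    X = np.zeros((4, 10))
    T = np.array([1, 1, 0, 0])
    mask = np.zeros((4, 4), dtype=bool)
    mask[[0, 1], 0] = True  # all of T=1 missing on x1
    with pytest.raises(ImputationError, match="x1"):
        treatment_mean_impute(_make_incomplete(X, T, mask))


@pytest.mark.parametrize(
    "imputer",
    [
        treatment_mean_impute,
        lambda s: regression_impute_pe(s, rng=1),
        lambda s: regression_impute_pe_pu(s, rng=2),
        lambda s: chained_equations_impute(s, m=3, n_cycles=3, rng=3),
        lambda s: chained_equations_impute(s, m=2, n_cycles=3, rng=3, model="norm"),
        lambda s: mimp_impute(s, m=3, min_count=50, n_cycles=3, rng=4),
    ],
    ids=["TMI", "SI_PE", "SI_PE_PU", "MI_pmm", "MI_norm", "MIMP"],
)
def test_observed_cells_bit_identical(incomplete_a, imputer):
    out = imputer(incomplete_a)
    X0 = incomplete_a.base.X
    for Xc in out.completed:
        assert Xc.shape == X0.shape
        obs = ~np.isnan(incomplete_a.masked_covariates())
        np.testing.assert_array_equal(Xc[obs], X0[obs])
        # fully observed columns are untouched entirely
        np.testing.assert_array_equal(Xc[:, 4:], X0[:, 4:])


def _single_cell_sample(n=150, seed=0):
    """A sample with exactly one missing cell (row 0 of x2)."""
    sample = generate_complete_sample(GeneratorConfig(n=n, scenario="A", seed=seed))
    mask = np.zeros((n, 4), dtype=bool)
    mask[0, 1] = True
    return IncompleteSample(base=sample, mask=mask, mechanism="manual")


def test_pe_imputation_noise_matches_residual_variance():
    """Imputed-value variance over repeated draws equals the fitted sigma^2."""
    import statsmodels.api as sm

    from psmiss.imputation import IMPUTER_COVARIATE_COLUMNS

    inc = _single_cell_sample()
    X, T, Y = inc.base.X, inc.base.T, inc.base.Y
    obs = np.ones(inc.n, dtype=bool)
    obs[0] = False
    preds = [c for c in IMPUTER_COVARIATE_COLUMNS if c != 1]
    D = np.column_stack([np.ones(inc.n), X[:, preds], T, Y])
    fit = sm.OLS(X[obs, 1], D[obs]).fit()
    draws = np.array(
        [
            regression_impute_pe(inc, rng=seed, n_cycles=1).completed[0][0, 1]
            for seed in range(10_000)
        ]
    )
    sigma2 = fit.mse_resid  # statsmodels oracle for the residual variance
    assert draws.var() == pytest.approx(sigma2, rel=0.05)
    assert draws.mean() == pytest.approx(fit.predict(D[:1])[0], abs=3 * np.sqrt(sigma2 / 10_000))


def test_pu_adds_parameter_uncertainty():
    """At small n the posterior-draw imputer is strictly more dispersed."""
    inc = _single_cell_sample(n=40, seed=3)
    pe = np.array(
        [regression_impute_pe(inc, rng=s, n_cycles=1).completed[0][0, 1] for s in range(4000)]
    )
    pu = np.array(
        [regression_impute_pe_pu(inc, rng=s, n_cycles=1).completed[0][0, 1] for s in range(4000)]
    )
    assert pu.var() > pe.var()


def test_mi_produces_m_datasets_with_between_variance(incomplete_a):
    out = chained_equations_impute(incomplete_a, m=5, n_cycles=3, rng=7)
    assert out.m == 5
    cell = np.argwhere(incomplete_a.mask[:, 0])[0][0]
    values = [Xc[cell, 0] for Xc in out.completed]
    assert np.var(values) > 0  # between-imputation variance strictly positive


def test_mi_identity_when_nothing_missing(sample_a):
    inc = IncompleteSample(base=sample_a, mask=np.zeros((sample_a.n, 4), bool), mechanism="none")
    out = chained_equations_impute(inc, m=1, n_cycles=2, rng=1)
    np.testing.assert_array_equal(out.completed[0], sample_a.X)


def test_mcar_imputation_preserves_marginal_mean():
    """Under MCAR the across-imputation mean of imputed x2 cells matches the
    complete-data mean of x2 (Monte-Carlo oracle)."""
    sample = generate_complete_sample(GeneratorConfig(n=5000, scenario="A", seed=31))
    inc = impose_mcar(sample, 0.25, np.random.default_rng(32))
    out = chained_equations_impute(inc, m=20, n_cycles=5, rng=33)
    mis = inc.mask[:, 1]
    pooled = np.concatenate([Xc[mis, 1] for Xc in out.completed])
    se = sample.X[:, 1].std() / np.sqrt(mis.sum())
    assert pooled.mean() == pytest.approx(sample.X[:, 1].mean(), abs=5 * se)


def test_pool_patterns_merge_trace():
    """Counts {1111: 400, 0111: 60, 1011: 70} with min_count=100: both small
    groups merge toward their Hamming-1 neighbour 1111."""
    rows = [[1, 1, 1, 1]] * 400 + [[0, 1, 1, 1]] * 60 + [[1, 0, 1, 1]] * 70
    mask = np.array(rows, dtype=bool)
    pooling = pool_patterns(mask, min_count=100)
    assert len(pooling.groups) == 1
    assert np.unique(pooling.ids).size == 1
    (sigs, count), = pooling.groups.values()
    assert count == 530


def test_pool_patterns_identity_and_stability():
    rng = np.random.default_rng(5)
    mask = rng.random((300, 4)) < 0.3
    raw = pool_patterns(mask, min_count=1)
    # min_count=1 keeps every raw signature as its own group
    sigs = (mask.astype(int) * np.array([8, 4, 2, 1])).sum(axis=1)
    assert len(raw.groups) == np.unique(sigs).size
    # all-complete data: a single trivial pattern
    none = pool_patterns(np.zeros((50, 4), dtype=bool), min_count=10)
    assert len(none.groups) == 1


def test_pool_patterns_respects_min_count():
    rng = np.random.default_rng(6)
    mask = rng.random((500, 4)) < 0.25
    pooling = pool_patterns(mask, min_count=100)
    for _, count in pooling.groups.values():
        assert count >= 100 or len(pooling.groups) == 1


def test_mimp_indicator_consistency(incomplete_a):
    out = mimp_impute(incomplete_a, m=3, min_count=50, n_cycles=2, rng=9)
    assert out.pattern_ids is not None and out.pattern_ids.shape == (incomplete_a.n,)
    # the indicator is a function of the mask only, identical across m
    again = mimp_impute(incomplete_a, m=2, min_count=50, n_cycles=2, rng=10)
    np.testing.assert_array_equal(out.pattern_ids, again.pattern_ids)
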