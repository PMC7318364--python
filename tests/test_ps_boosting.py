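"""Boosted propensity trees: split search, surrogates, AASM, stopping."""

import numpy as np
import pytest
from _reference import build_cart, enumerate_best_split, predict_cart

from psmiss.ps_boosting import (
    BoostConfig,
    boost,
    compute_aasm,
    fit_tree,
    predict_ps,
)
from psmiss.synthetic_data import GeneratorConfig, generate_complete_sample


def _random_fixture(rng, n, k=4):
    """Mixed binary/continuous covariates and residual-like responses."""
    X = rng.standard_normal((n, k))
    X[:, ::2] = (X[:, ::2] > 0.3).astype(float)
    r = rng.standard_normal(n) * 0.3
    return X, r


def test_depth_one_split_matches_enumeration():
    rng = np.random.default_rng(81)
    X, r = _random_fixture(rng, 8)
    cfg = BoostConfig(depth=1, min_node=2, max_iterations=1)
    tree = fit_tree(X, r, cfg)
    v, thr, _ = enumerate_best_split(X, r, min_obs=2)
    assert tree.feature[0] == v
    assert tree.threshold[0] == pytest.approx(thr)
    # node means match the enumerated partition
    left = X[:, v] <= thr
    assert tree.value[tree.left[0]] == pytest.approx(r[left].mean())
    assert tree.value[tree.right[0]] == pytest.approx(r[~left].mean())


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("depth", [1, 2, 4])
def test_tree_equals_bruteforce_on_small_fixtures(seed, depth):
    """Best-first growth with exhaustive splits == slow reference on <=50 rows."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 51))
    X, r = _random_fixture(rng, n)
    cfg = BoostConfig(depth=depth, min_node=2, max_iterations=1)
    tree = fit_tree(X, r, cfg)
    ref = build_cart_best_first(X, r, depth, min_obs=2)
    np.testing.assert_allclose(tree.predict(X), ref_predict(ref, X), atol=1e-10)


def build_cart_best_first(X, r, max_splits, min_obs):
    """Independent best-first reference: repeatedly split the open leaf with
    the largest exhaustive-search gain."""
    leaves = [{"rows": np.arange(X.shape[0]), "value": float(r.mean())}]
    for leaf in leaves:
        leaf["cand"] = enumerate_best_split(X[leaf["rows"]], r[leaf["rows"]], min_obs)
    splits = []
    for _ in range(max_splits):
        open_ = [lf for lf in leaves if lf.get("cand")]
        if not open_:
            break
        best = max(open_, key=lambda lf: lf["cand"][2])
        v, thr, _ = best["cand"]
        rows = best["rows"]
        go_left = X[rows, v] <= thr
        left = {"rows": rows[go_left], "value": float(r[rows[go_left]].mean())}
        right = {"rows": rows[~go_left], "value": float(r[rows[~go_left]].mean())}
        for lf in (left, right):
            lf["cand"] = enumerate_best_split(X[lf["rows"]], r[lf["rows"]], min_obs)
        leaves = [lf for lf in leaves if lf is not best] + [left, right]
        splits.append((v, thr))
    return leaves


def ref_predict(leaves, X):
    out = np.empty(X.shape[0])
    for leaf in leaves:
        out[leaf["rows"]] = leaf["value"]
    return out


def test_missing_primary_split_matches_nan_aware_enumeration():
    rng = np.random.default_rng(92)
    X, r = _random_fixture(rng, 40)
    X[rng.random(X.shape) < 0.2] = np.nan
    cfg = BoostConfig(depth=1, min_node=2, max_iterations=1)
    tree = fit_tree(X, r, cfg)
    v, thr, _ = enumerate_best_split(X, r, min_obs=2)
    assert tree.feature[0] == v
    assert tree.threshold[0] == pytest.approx(thr)


def test_complete_data_ignores_surrogate_machinery():
    rng = np.random.default_rng(83)
    X, r = _random_fixture(rng, 50)
    cfg = BoostConfig(depth=3, min_node=2, max_iterations=1)
    with_surr = fit_tree(X, r, cfg)
    no_surr = fit_tree(X, r, BoostConfig(depth=3, min_node=2, max_surrogates=0,
                                         max_iterations=1))
    np.testing.assert_array_equal(with_surr.predict(X), no_surr.predict(X))
    assert with_surr.n_surr[: with_surr.n_nodes].sum() == 0


def test_duplicate_column_is_perfect_surrogate():
    rng = np.random.default_rng(84)
    x = rng.standard_normal(60)
    r = (x > 0).astype(float) + rng.standard_normal(60) * 0.05
    X = np.column_stack([x, x.copy(), rng.standard_normal(60)])
    X[:6, 0] = np.nan  # primary missing for some rows; duplicate fully observed
    tree = fit_tree(X, r, BoostConfig(depth=1, min_node=2, max_iterations=1))
    d = tree.as_dict()
    assert not d["leaf"]
    assert d["feature"] in (0, 1)
    assert d["surrogates"], "a perfect duplicate must be stored as surrogate"
    top = d["surrogates"][0]
    assert top["feature"] == 1 - d["feature"]
    assert top["agreement"] == pytest.approx(1.0)
    # rows missing on the primary are routed exactly as the duplicate dictates
    X_full = X.copy()
    X_full[:6, 0] = X[:6, 1]
    np.testing.assert_array_equal(tree.predict(X), tree.predict(X_full))


def test_surrogate_agreement_exceeds_majority_rule():
    rng = np.random.default_rng(85)
    sample = generate_complete_sample(GeneratorConfig(n=400, scenario="A", seed=86))
    X = sample.X[:, :4].copy()
    X[rng.random(X.shape) < 0.25] = np.nan
    resid = sample.T - sample.T.mean()
    tree = fit_tree(X, resid, BoostConfig(depth=4, max_iterations=1))
    checked = 0
    for nid in range(tree.n_nodes):
        if tree.feature[nid] < 0:
            continue
        agreements = tree.s_agr[nid, : tree.n_surr[nid]]
        assert np.all(agreements > tree.maj_agree[nid])
        assert np.all(np.diff(agreements) <= 0)  # ordered by decreasing agreement
        checked += 1
    assert checked > 0


def test_all_split_variables_missing_routes_by_majority_or_surrogate():
    rng = np.random.default_rng(87)
    X, r = _random_fixture(rng, 50)
    X[0, :] = np.nan  # one row with every covariate missing
    tree = fit_tree(X, r, BoostConfig(depth=2, min_node=2, max_iterations=1))
    # reference walk: missing everywhere -> always the majority direction
    nid = 0
    while tree.feature[nid] >= 0:
        nid = tree.left[nid] if tree.maj_left[nid] else tree.right[nid]
    assert tree.predict(X[:1])[0] == tree.value[nid]


def test_boost_zero_iterations_gives_prevalence(sample_a):
    model = boost(sample_a.X[:, :4], sample_a.T, BoostConfig(max_iterations=0))
    np.testing.assert_allclose(model.ps, sample_a.T.mean(), atol=1e-12)
    assert model.best_iteration == 0


def test_boost_vanishing_shrinkage_stays_near_prevalence(sample_a):
    model = boost(sample_a.X[:, :4], sample_a.T,
                  BoostConfig(shrinkage=1e-8, max_iterations=5))
    np.testing.assert_allclose(model.ps, sample_a.T.mean(), atol=1e-6)


def test_training_ps_reproduced_by_predict(sample_a, incomplete_a):
    for X in (sample_a.X[:, :4], incomplete_a.masked_covariates()[:, :4]):
        model = boost(X, sample_a.T, BoostConfig(max_iterations=40))
        np.testing.assert_array_equal(
            predict_ps(model, X, model.best_iteration), model.ps
        )


def test_loglikelihood_increases_early(sample_a):
    X, T = sample_a.X[:, :4], sample_a.T
    model = boost(X, T, BoostConfig(max_iterations=30))
    g = np.full(sample_a.n, model.g0)
    def loglik(g):
        return float(T @ g - np.logaddexp(0, g).sum())
    lls = [loglik(g)]
    for tree in model.trees:
        g = g + model.shrinkage * tree.predict(X)
        lls.append(loglik(g))
    assert np.all(np.diff(lls) > 0)


def test_aasm_hand_example():
    # exposed {1, 3}: mean 2, sd sqrt(2); unexposed {0, 2} with unit odds
    # weights (ps = 0.5): weighted mean 1 -> AASM = 1/sqrt(2)
    X = np.array([1.0, 3.0, 0.0, 2.0])
    T = np.array([1, 1, 0, 0])
    ps = np.full(4, 0.5)
    assert compute_aasm(X, T, ps) == pytest.approx(1 / np.sqrt(2))


def test_aasm_balance_and_weight_scale_invariance():
    X = np.array([1.0, 3.0, 1.0, 3.0])
    T = np.array([1, 1, 0, 0])
    assert compute_aasm(X, T, np.full(4, 0.5)) == pytest.approx(0.0)
    # doubling all unexposed odds weights leaves the metric unchanged
    X = np.array([1.0, 3.0, 0.0, 2.0])
    a1 = compute_aasm(X, T, np.array([0.5, 0.5, 1 / 3, 1 / 3]))  # w = 0.5
    a2 = compute_aasm(X, T, np.array([0.5, 0.5, 0.5, 0.5]))      # w = 1
    assert a1 == pytest.approx(a2)


def test_aasm_errors_on_degenerate_exposed_group():
    with pytest.raises(ValueError):
        compute_aasm(np.array([1.0, 1.0, 0.0, 2.0]), np.array([1, 1, 0, 0]),
                     np.full(4, 0.5))


def test_aasm_improves_from_null_model():
    sample = generate_complete_sample(GeneratorConfig(n=1000, scenario="G", seed=88))
    model = boost(sample.X[:, :4], sample.T, BoostConfig(max_iterations=400))
    best = model.aasm_trajectory[model.best_iteration]
    assert best < model.aasm_trajectory[0]
    assert model.best_iteration == np.argmin(model.aasm_trajectory)


def test_predict_ps_iteration_bounds(sample_a):
    model = boost(sample_a.X[:, :4], sample_a.T, BoostConfig(max_iterations=5))
    with pytest.raises(ValueError):
        predict_ps(model, sample_a.X[:, :4], iteration=6)
    np.testing.assert_allclose(
        predict_ps(model, sample_a.X[:, :4], iteration=0), sample_a.T.mean(),
        atol=1e-12,
    )


def test_tree_export_round_trip():
    rng = np.random.default_rng(89)
    X, r = _random_fixture(rng, 30)
    tree = fit_tree(X, r, BoostConfig(depth=2, min_node=2, max_iterations=1))
    d = tree.as_dict()
    assert isinstance(d, dict) and "leaf" in d
    import json

    json.dumps(d)  # exportable as a JSON tree listing
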