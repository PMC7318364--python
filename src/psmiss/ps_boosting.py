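"""Gradient-boosted regression trees for propensity scores, tolerant of
missing covariate values via surrogate splits.

The model is stagewise boosting of the Bernoulli log-likelihood of the
exposure: starting from the average log-odds g0 = logit(mean(T)), each
iteration fits a small least-squares regression tree to the current
residuals T - expit(g) — grown best-first to the interaction depth, i.e.
the number of splits — and updates g by a shrunken step
g <- g + alpha * h(X).  Terminal-node values are the one-step Newton
estimates sum(residual) / sum(p(1-p)) over the leaf.  Missing values
never exclude a row: the split search uses the
cells observed on the candidate variable, and rows missing the chosen
split variable are routed by surrogate splits or, failing those, by the
node's majority direction.

The returned propensity scores come from the boosting iteration that
minimizes the average absolute standardized mean difference (AASM) between
exposure groups over the model covariates, with odds weights
w = p/(1 - p) applied to the unexposed means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit

from ._tree import aasm_kernel, boost_update, grow_tree, predict_tree, presort

__all__ = [
    "BoostConfig",
    "Tree",
    "BoostedModel",
    "fit_tree",
    "boost",
    "compute_aasm",
    "predict_ps",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoostConfig:
    """Tuning parameters of the boosted propensity model.

    shrinkage : step size alpha in (0, 1]; 0.05 for reproduction runs.
    depth : interaction depth — the number of splits per tree, grown
        best-first (depth 4 gives 5-leaf trees supporting four-way
        interactions).
    max_iterations : boosting budget; AASM is evaluated at every iteration.
    bag_fraction : row subsampling per stage (1.0 = none, reproducible).
    min_node : minimum observations per child node.
    max_surrogates : surrogate splits stored per node.
    """

    shrinkage: float = 0.05
    depth: int = 4
    max_iterations: int = 10_000
    bag_fraction: float = 1.0
    min_node: int = 10
    max_surrogates: int = 5
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in (0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


class Tree:
    """A fitted regression tree in flat-array form."""

    __slots__ = (
        "n_nodes", "feature", "threshold", "value", "left", "right",
        "maj_left", "n_surr", "s_feat", "s_thr", "s_dir", "s_agr",
        "maj_agree",
    )

    def __init__(self, n_nodes, feature, threshold, value, left, right,
                 maj_left, n_surr, s_feat, s_thr, s_dir, s_agr, maj_agree):
        self.n_nodes = n_nodes
        self.feature = feature
        self.threshold = threshold
        self.value = value
        self.left = left
        self.right = right
        self.maj_left = maj_left
        self.n_surr = n_surr
        self.s_feat = s_feat
        self.s_thr = s_thr
        self.s_dir = s_dir
        self.s_agr = s_agr
        self.maj_agree = maj_agree

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.empty(X.shape[0])
        predict_tree(X, self.feature, self.threshold, self.value, self.left,
                     self.right, self.maj_left, self.n_surr, self.s_feat,
                     self.s_thr, self.s_dir, out)
        return out

    def as_dict(self, nid: int = 0) -> dict:
        """Nested-dict listing of the tree for inspection/export."""
        if self.feature[nid] < 0:
            return {"leaf": True, "value": float(self.value[nid])}
        return {
            "leaf": False,
            "feature": int(self.feature[nid]),
            "threshold": float(self.threshold[nid]),
            "value": float(self.value[nid]),
            "majority": "left" if self.maj_left[nid] else "right",
            "majority_agreement": float(self.maj_agree[nid]),
            "surrogates": [
                {
                    "feature": int(self.s_feat[nid, s]),
                    "threshold": float(self.s_thr[nid, s]),
                    "left_if_le": bool(self.s_dir[nid, s]),
                    "agreement": float(self.s_agr[nid, s]),
                }
                for s in range(self.n_surr[nid])
            ],
            "left": self.as_dict(int(self.left[nid])),
            "right": self.as_dict(int(self.right[nid])),
        }


@dataclass
class BoostedModel:
    """A fitted boosted propensity model with its AASM trajectory."""

    g0: float
    shrinkage: float
    trees: list
    aasm_trajectory: np.ndarray
    best_iteration: int
    ps: np.ndarray  # training propensity scores at the best iteration
    config: BoostConfig = field(default=None)

    @property
    def n_iterations(self) -> int:
        return len(self.trees)

    def trajectory_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iteration": np.arange(self.aasm_trajectory.size),
             "aasm": self.aasm_trajectory}
        )


def fit_tree(X: np.ndarray, residuals: np.ndarray, cfg: BoostConfig) -> Tree:
    """Fit one least-squares tree (public split-search entry point)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    r = np.ascontiguousarray(residuals, dtype=np.float64)
    tree, _ = _fit_tree_with_pred(X, r, np.ones(X.shape[0]), cfg,
                                  bool(np.isnan(X).any()), presort(X))
    return tree


def _fit_tree_with_pred(X, r, w, cfg, has_missing, sidx):
    max_nodes = 2 * cfg.depth + 1
    feature = np.empty(max_nodes, np.int64)
    threshold = np.empty(max_nodes)
    value = np.empty(max_nodes)
    left = np.empty(max_nodes, np.int64)
    right = np.empty(max_nodes, np.int64)
    maj_left = np.empty(max_nodes, np.uint8)
    n_surr = np.empty(max_nodes, np.int64)
    s_feat = np.zeros((max_nodes, cfg.max_surrogates), np.int64)
    s_thr = np.zeros((max_nodes, cfg.max_surrogates))
    s_dir = np.zeros((max_nodes, cfg.max_surrogates), np.uint8)
    s_agr = np.zeros((max_nodes, cfg.max_surrogates))
    maj_agree = np.zeros(max_nodes)
    pred = np.empty(X.shape[0])
    n_nodes = grow_tree(X, r, w, sidx, cfg.depth, cfg.min_node,
                        cfg.max_surrogates, has_missing, feature, threshold,
                        value, left, right, maj_left, n_surr, s_feat, s_thr,
                        s_dir, s_agr, maj_agree, pred)
    tree = Tree(int(n_nodes), feature, threshold, value, left, right,
                maj_left, n_surr, s_feat, s_thr, s_dir, s_agr, maj_agree)
    return tree, pred


def compute_aasm(X: np.ndarray, T: np.ndarray, ps: np.ndarray) -> float:
    """AASM over the columns of X (pairwise-complete cells when missing)."""
    X = np.ascontiguousarray(np.atleast_2d(X.T).T, dtype=np.float64)
    ps = np.asarray(ps, dtype=float)
    if np.any(ps <= 0.0) or np.any(ps >= 1.0):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    out = aasm_kernel(X, np.ascontiguousarray(T, dtype=np.int64), ps)
    if np.isnan(out):
        raise ValueError("no covariate with positive exposed-group variance")
    return float(out)


def boost(X: np.ndarray, T: np.ndarray, cfg: BoostConfig | None = None,
          rng=None) -> BoostedModel:
    """Boost the Bernoulli log-likelihood; stop at the AASM minimum.

    `X` holds the model covariates (NaN marks a missing cell); the same
    columns are used for the balance metric.
    """
    if cfg is None:
        cfg = BoostConfig()
    X = np.ascontiguousarray(X, dtype=np.float64)
    Tf = np.asarray(T, dtype=float)
    Ti = np.ascontiguousarray(T, dtype=np.int64)
    if Ti.min() == Ti.max():
        raise ValueError("exposure vector must contain both classes")
    n = X.shape[0]
    has_missing = bool(np.isnan(X).any())
    sidx0 = presort(X)
    p_bar = Tf.mean()
    g0 = float(logit(p_bar))
    g = np.full(n, g0)
    ps = np.empty(n)
    boost_update(g, np.zeros(n), 0.0, ps)  # ps = expit(g0)
    traj = np.empty(cfg.max_iterations + 1)
    traj[0] = aasm_kernel(X, Ti, ps)
    best_it = 0
    best_aasm = traj[0]
    ps_best = ps.copy()
    trees = []
    if cfg.bag_fraction < 1.0:
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    for it in range(1, cfg.max_iterations + 1):
        resid = Tf - ps
        hess = ps * (1.0 - ps)
        if cfg.bag_fraction < 1.0:
            rows = rng.choice(n, size=max(2, int(round(cfg.bag_fraction * n))),
                              replace=False)
            Xs = np.ascontiguousarray(X[rows])
            tree, _ = _fit_tree_with_pred(Xs, resid[rows], hess[rows], cfg,
                                          has_missing, presort(Xs))
            pred = tree.predict(X)
        else:
            tree, pred = _fit_tree_with_pred(X, resid, hess, cfg, has_missing,
                                             sidx0.copy())
        boost_update(g, pred, cfg.shrinkage, ps)
        a = aasm_kernel(X, Ti, ps)
        traj[it] = a
        if a < best_aasm:
            best_aasm = a
            best_it = it
            ps_best = ps.copy()
        trees.append(tree)
    if cfg.max_iterations > 0 and best_it == cfg.max_iterations:
        logger.warning(
            "AASM minimizer is the final iteration (%d); the minimum may lie "
            "beyond the boosting budget", best_it,
        )
    return BoostedModel(g0=g0, shrinkage=cfg.shrinkage, trees=trees,
                        aasm_trajectory=traj, best_iteration=best_it,
                        ps=ps_best, config=cfg)


def predict_ps(model: BoostedModel, X: np.ndarray,
               iteration: int | None = None) -> np.ndarray:
    """Propensity scores at a given iteration (default: the AASM-best one)."""
    if iteration is None:
        iteration = model.best_iteration
    if iteration > len(model.trees):
        raise ValueError(
            f"iteration {iteration} exceeds fitted iterations {len(model.trees)}"
        )
    X = np.ascontiguousarray(X, dtype=np.float64)
    g = np.full(X.shape[0], model.g0)
    ps = np.empty(X.shape[0])
    boost_update(g, np.zeros(X.shape[0]), 0.0, ps)
    for tree in model.trees[:iteration]:
        boost_update(g, tree.predict(X), model.shrinkage, ps)
    return ps
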