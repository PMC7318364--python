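"""Independent slow reference implementations used as test oracles.

These deliberately avoid the package's tree kernels: splits are found by
exhaustive enumeration of every (variable, threshold) pair, trees are
built by plain recursion, and predictions by dict walking.
"""

import numpy as np


def enumerate_best_split(X, r, min_obs):
    """Exhaustive search of the SSE-reducing split over complete cases.

    Scans variables in index order and thresholds in ascending order,
    keeping a candidate only on strict improvement; thresholds are
    midpoints between consecutive distinct observed values.  Returns
    (var, threshold, gain) or None.
    """
    best = None
    best_gain = 1e-12
    for v in range(X.shape[1]):
        obs = ~np.isnan(X[:, v])
        xv = X[obs, v]
        rv = r[obs]
        cnt = xv.size
        if cnt < 2 * min_obs:
            continue
        order = np.argsort(xv, kind="stable")
        xs, rs = xv[order], rv[order]
        tot = 0.0
        for val in rs:
            tot += val
        base = tot * tot / cnt
        run = 0.0
        for i in range(cnt - 1):
            run += rs[i]
            if xs[i + 1] == xs[i]:
                continue
            nl, nr = i + 1, cnt - i - 1
            if nl < min_obs or nr < min_obs:
                continue
            gain = run * run / nl + (tot - run) ** 2 / nr - base
            if gain > best_gain:
                best_gain = gain
                best = (v, 0.5 * (xs[i] + xs[i + 1]), gain)
    return best


def build_cart(X, r, depth, min_obs):
    """Recursive exhaustive-search CART for complete data (no surrogates)."""
    node = {"value": float(r.mean()), "n": X.shape[0]}
    if depth == 0 or X.shape[0] < 2 * min_obs:
        return node
    found = enumerate_best_split(X, r, min_obs)
    if found is None:
        return node
    v, thr, _ = found
    go_left = X[:, v] <= thr
    node.update(var=v, thr=thr)
    node["left"] = build_cart(X[go_left], r[go_left], depth - 1, min_obs)
    node["right"] = build_cart(X[~go_left], r[~go_left], depth - 1, min_obs)
    return node


def predict_cart(node, X):
    out = np.empty(X.shape[0])
    for i, row in enumerate(X):
        nd = node
        while "var" in nd:
            nd = nd["left"] if row[nd["var"]] <= nd["thr"] else nd["right"]
        out[i] = nd["value"]
    return out


def wls_fit(Y, T, w):
    """Weighted least squares of Y on (1, T) via explicit normal equations."""
    D = np.column_stack([np.ones_like(Y), T.astype(float)])
    W = np.diag(w)
    A = D.T @ W @ D
    beta = np.linalg.solve(A, D.T @ W @ Y)
    resid = Y - D @ beta
    sigma2 = float(resid @ W @ resid) / (Y.size - 2)
    cov = sigma2 * np.linalg.inv(A)
    return beta[1], np.sqrt(cov[1, 1])
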