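"""Numba kernels for boosted regression trees with surrogate splits.

Trees are grown *best-first*: starting from the root, the terminal node
whose best split yields the largest SSE reduction is split next, until the
split budget (the interaction depth) is exhausted.  Splits are
least-squares: each candidate maximizes the SSE reduction of the residuals
computed over the rows observed on the candidate variable; ties keep the
earlier candidate (lower variable index, then lower threshold, then the
earlier-created node).  Rows missing the chosen split variable are routed
by the best surviving surrogate — a split on another variable whose
agreement with the primary partition (in either direction) strictly
exceeds the "go with the majority" rule — and by the majority direction
when every surrogate is missing too.

The split search never sorts: callers supply one per-variable ordering of
the rows (NaNs last), computed once per dataset, which the grower
partitions stably as nodes split so every node segment stays sorted.
"""

import numpy as np
from numba import njit

LEAF = -1


def presort(X: np.ndarray) -> np.ndarray:
    """Per-variable row orderings (k, n), NaNs placed last."""
    return np.argsort(X, axis=0, kind="stable").T.copy()


@njit(cache=True)
def _route_left(X, i, nid, feature, threshold, maj_left, n_surr, s_feat, s_thr, s_dir):
    x = X[i, feature[nid]]
    if not np.isnan(x):
        return x <= threshold[nid]
    for s in range(n_surr[nid]):
        xs = X[i, s_feat[nid, s]]
        if not np.isnan(xs):
            if s_dir[nid, s] == 1:
                return xs <= s_thr[nid, s]
            return xs > s_thr[nid, s]
    return maj_left[nid] == 1


@njit(cache=True)
def _eval_split(X, r, sidx, s, e, min_obs, has_missing, xbuf, rbuf):
    """Best (gain, var, thr, nl, cnt) over all variables for one node.

    Gains are SSE reductions over the rows observed on the candidate
    variable; returns var = -1 when no admissible split exists.
    """
    best_gain = 1e-12
    best_var = -1
    best_thr = 0.0
    best_nl = 0
    best_cnt = 0
    k = sidx.shape[0]
    for v in range(k):
        cnt = 0
        tot_v = 0.0
        for t in range(s, e):
            row = sidx[v, t]
            x = X[row, v]
            if has_missing and np.isnan(x):
                break
            xbuf[cnt] = x
            rbuf[cnt] = r[row]
            tot_v += rbuf[cnt]
            cnt += 1
        if cnt < 2 * min_obs:
            continue
        base = tot_v * tot_v / cnt
        run = 0.0
        hi = cnt - min_obs
        for i2 in range(cnt - 1):
            run += rbuf[i2]
            x_here = xbuf[i2]
            x_next = xbuf[i2 + 1]
            if x_next == x_here:
                continue
            nl = i2 + 1
            if nl < min_obs or nl > hi:
                continue
            nr = cnt - nl
            gain = run * run / nl + (tot_v - run) * (tot_v - run) / nr - base
            if gain > best_gain:
                best_gain = gain
                best_var = v
                best_thr = 0.5 * (x_here + x_next)
                best_nl = nl
                best_cnt = cnt
    return best_gain, best_var, best_thr, best_nl, best_cnt


@njit(cache=True)
def grow_tree(X, r, w, sidx, max_splits, min_obs, max_surr, has_missing,
              feature, threshold, value, left, right, maj_left,
              n_surr, s_feat, s_thr, s_dir, s_agr, maj_agree_out, pred):
    """Grow one best-first tree; fills the node arrays and training preds.

    Splits minimize the SSE of the residuals ``r``; node values are the
    weighted estimates sum(r)/sum(w) (``w`` = 1 gives mean residuals; the
    Bernoulli boosting caller passes w = p(1-p) for a Newton step).
    ``sidx`` (k, n) holds per-variable sorted row indices and is consumed
    (partitioned in place).  Returns the number of nodes used.
    """
    n, k = X.shape
    max_nodes = feature.shape[0]
    for i in range(max_nodes):
        feature[i] = LEAF
        left[i] = LEAF
        right[i] = LEAF
        n_surr[i] = 0
        maj_left[i] = 1
        value[i] = 0.0
        threshold[i] = 0.0
    side = np.empty(n, np.uint8)
    buf = np.empty(n, np.int64)
    xbuf = np.empty(n)
    rbuf = np.empty(n)
    mbuf = np.empty(n, np.uint8)
    # open terminal nodes and their candidate splits
    cap = max_splits + 1
    ol_node = np.empty(cap, np.int64)
    ol_s = np.empty(cap, np.int64)
    ol_e = np.empty(cap, np.int64)
    ol_gain = np.empty(cap)
    ol_var = np.empty(cap, np.int64)
    ol_thr = np.empty(cap)
    ol_nl = np.empty(cap, np.int64)
    ol_cnt = np.empty(cap, np.int64)

    tot = 0.0
    tot_w = 0.0
    for i in range(n):
        tot += r[i]
        tot_w += w[i]
    value[0] = tot / tot_w if tot_w > 1e-300 else 0.0
    g0, v0, thr0, nl0, cnt0 = _eval_split(X, r, sidx, 0, n, min_obs,
                                          has_missing, xbuf, rbuf)
    ol_node[0] = 0
    ol_s[0] = 0
    ol_e[0] = n
    ol_gain[0] = g0
    ol_var[0] = v0
    ol_thr[0] = thr0
    ol_nl[0] = nl0
    ol_cnt[0] = cnt0
    n_open = 1
    node_count = 1
    for _ in range(max_splits):
        # pick the open node with the largest admissible gain
        bi = -1
        bg = 0.0
        for c in range(n_open):
            if ol_var[c] >= 0 and ol_gain[c] > bg:
                bg = ol_gain[c]
                bi = c
        if bi < 0:
            break
        nid = ol_node[bi]
        s = ol_s[bi]
        e = ol_e[bi]
        m = e - s
        best_var = ol_var[bi]
        best_thr = ol_thr[bi]
        best_nl = ol_nl[bi]
        best_cnt = ol_cnt[bi]
        nl_o = best_nl
        nr_o = best_cnt - best_nl
        maj_left[nid] = 1 if nl_o >= nr_o else 0
        maj_agree = max(nl_o, nr_o) / (nl_o + nr_o)
        maj_agree_out[nid] = maj_agree
        feature[nid] = best_var
        threshold[nid] = best_thr
        if has_missing and max_surr > 0:
            # candidate surrogate per other variable: best-agreement split
            nc = 0
            cand_feat = np.empty(k, np.int64)
            cand_thr = np.empty(k)
            cand_dir = np.empty(k, np.uint8)
            cand_agr = np.empty(k)
            for u in range(k):
                if u == best_var:
                    continue
                # rows observed on both u and the primary, in u order
                cnt = 0
                totL = 0
                for t in range(s, e):
                    row = sidx[u, t]
                    xu = X[row, u]
                    if np.isnan(xu):
                        break
                    xp = X[row, best_var]
                    if np.isnan(xp):
                        continue
                    xbuf[cnt] = xu
                    if xp <= best_thr:
                        mbuf[cnt] = 1
                        totL += 1
                    else:
                        mbuf[cnt] = 0
                    cnt += 1
                if cnt < 2:
                    continue
                runL = 0
                ba = -1.0
                bt = 0.0
                bd = np.uint8(1)
                for i2 in range(cnt - 1):
                    runL += mbuf[i2]
                    if xbuf[i2 + 1] == xbuf[i2]:
                        continue
                    nl = i2 + 1
                    # forward: u <= thr goes left
                    fwd = (runL + (cnt - nl - (totL - runL))) / cnt
                    rev = 1.0 - fwd
                    if fwd >= rev:
                        a = fwd
                        dd = np.uint8(1)
                    else:
                        a = rev
                        dd = np.uint8(0)
                    if a > ba:
                        ba = a
                        bt = 0.5 * (xbuf[i2] + xbuf[i2 + 1])
                        bd = dd
                if ba > maj_agree:
                    cand_feat[nc] = u
                    cand_thr[nc] = bt
                    cand_dir[nc] = bd
                    cand_agr[nc] = ba
                    nc += 1
            # keep the top max_surr by agreement (stable in variable order)
            kept = 0
            used = np.zeros(nc, np.uint8)
            while kept < max_surr and kept < nc:
                sb = -1
                sv = -1.0
                for c in range(nc):
                    if used[c] == 0 and cand_agr[c] > sv:
                        sv = cand_agr[c]
                        sb = c
                used[sb] = 1
                s_feat[nid, kept] = cand_feat[sb]
                s_thr[nid, kept] = cand_thr[sb]
                s_dir[nid, kept] = cand_dir[sb]
                s_agr[nid, kept] = cand_agr[sb]
                kept += 1
            n_surr[nid] = kept
        # route node rows: rows observed on the primary variable sit at the
        # head of its segment (first best_nl go left); only the NaN tail
        # needs the surrogate/majority rules
        nl_t = best_nl
        for t in range(s, s + best_nl):
            side[sidx[best_var, t]] = 1
        for t in range(s + best_nl, s + best_cnt):
            side[sidx[best_var, t]] = 0
        for t in range(s + best_cnt, e):
            row = sidx[best_var, t]
            if _route_left(X, row, nid, feature, threshold, maj_left, n_surr,
                           s_feat, s_thr, s_dir):
                side[row] = 1
                nl_t += 1
            else:
                side[row] = 0
        nr_t = m - nl_t
        if nl_t == 0 or nr_t == 0:
            # routing degenerate: withdraw the split, close the node
            feature[nid] = LEAF
            n_surr[nid] = 0
            ol_var[bi] = -1
            continue
        # stable partition of every variable's segment
        for v in range(k):
            a = 0
            b = 0
            for t in range(s, e):
                row = sidx[v, t]
                if side[row] == 1:
                    buf[a] = row
                    a += 1
                else:
                    b += 1
                    buf[m - b] = row
            for t in range(a):
                sidx[v, s + t] = buf[t]
            for t in range(b):
                sidx[v, s + a + t] = buf[m - 1 - t]
        lid = node_count
        rid = node_count + 1
        node_count += 2
        left[nid] = lid
        right[nid] = rid
        # children: values, candidate splits, open-list bookkeeping
        cs = s
        ce = s + nl_t
        for child in (lid, rid):
            ctot = 0.0
            ctot_w = 0.0
            for t in range(cs, ce):
                row = sidx[0, t]
                ctot += r[row]
                ctot_w += w[row]
            value[child] = ctot / ctot_w if ctot_w > 1e-300 else 0.0
            cg, cv, cthr, cnl, ccnt = _eval_split(X, r, sidx, cs, ce, min_obs,
                                                  has_missing, xbuf, rbuf)
            if child == lid:
                # left child replaces the parent's open slot
                slot = bi
            else:
                slot = n_open
                n_open += 1
            ol_node[slot] = child
            ol_s[slot] = cs
            ol_e[slot] = ce
            ol_gain[slot] = cg
            ol_var[slot] = cv
            ol_thr[slot] = cthr
            ol_nl[slot] = cnl
            ol_cnt[slot] = ccnt
            cs = ce
            ce = e
    # fill training predictions from the remaining terminal segments
    for c in range(n_open):
        nid = ol_node[c]
        val = value[nid]
        for t in range(ol_s[c], ol_e[c]):
            pred[sidx[0, t]] = val
    return node_count


@njit(cache=True)
def predict_tree(X, feature, threshold, value, left, right, maj_left,
                 n_surr, s_feat, s_thr, s_dir, out):
    n = X.shape[0]
    for i in range(n):
        nid = 0
        while feature[nid] != LEAF:
            if _route_left(X, i, nid, feature, threshold, maj_left, n_surr,
                           s_feat, s_thr, s_dir):
                nid = left[nid]
            else:
                nid = right[nid]
        out[i] = value[nid]


@njit(cache=True)
def aasm_kernel(Xb, T, ps):
    """Average absolute standardized mean difference, odds-weighted controls.

    Covariates with missing values use pairwise-complete cells; covariates
    with zero exposed-group variance are skipped.  Returns NaN when no
    covariate is usable.
    """
    n, k = Xb.shape
    tot = 0.0
    used = 0
    for j in range(k):
        s1 = 0.0
        ss1 = 0.0
        n1 = 0
        sw = 0.0
        swx = 0.0
        for i in range(n):
            x = Xb[i, j]
            if np.isnan(x):
                continue
            if T[i] == 1:
                s1 += x
                ss1 += x * x
                n1 += 1
            else:
                w = ps[i] / (1.0 - ps[i])
                sw += w
                swx += w * x
        if n1 < 2 or sw <= 0.0:
            continue
        m1 = s1 / n1
        var1 = (ss1 - n1 * m1 * m1) / (n1 - 1)
        if var1 <= 0.0:
            continue
        tot += abs(m1 - swx / sw) / np.sqrt(var1)
        used += 1
    if used == 0:
        return np.nan
    return tot / used


@njit(cache=True)
def boost_update(g, pred, shrinkage, ps):
    """g += shrinkage * pred; ps = expit(g) in one pass."""
    for i in range(g.shape[0]):
        g[i] += shrinkage * pred[i]
        ps[i] = 1.0 / (1.0 + np.exp(-g[i]))
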