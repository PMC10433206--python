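"""Weighted CART regression trees with per-split weighted feature sampling.

The tree core is custom because the iterative-forest procedure needs two
things an off-the-shelf tree does not expose: (a) the candidate feature
set at every split is sampled *with probability proportional to the
current feature weights*, and (b) every split records the mean feature
value and mean outcome of both children, which the directionality stage
regresses against each other.

Split search is histogram-based: each feature is discretized once per
fit into at most ``max_bins`` bins.  When a feature has no more distinct
values than bins (always true at small n), the binned search is exactly
the classical exhaustive search over midpoints of adjacent distinct
values; on larger data the candidate thresholds are quantile cut points.
Rows carry weights, so identical rows (all patients of one ZIP code) can
be collapsed to a single weighted row without changing any split
statistic: the SSE reduction of a candidate split depends only on the
per-side weight and outcome sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_EPS_GAIN = 1e-12


@njit(cache=True)
def _build_tree(codes, xvals, w, ysum, ysq, n_bins, thr_flat, thr_off,
                fweights, m_try, min_leaf, seed, max_nodes):
    n, F = codes.shape
    feat = np.full(max_nodes, -1, np.int32)
    thr = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int32)
    right = np.full(max_nodes, -1, np.int32)
    value = np.zeros(max_nodes)
    nodew = np.zeros(max_nodes)
    gain_a = np.zeros(max_nodes)
    wl_a = np.zeros(max_nodes)
    wr_a = np.zeros(max_nodes)
    myl_a = np.zeros(max_nodes)
    myr_a = np.zeros(max_nodes)
    mxl_a = np.zeros(max_nodes)
    mxr_a = np.zeros(max_nodes)

    order = np.arange(n)
    tmp = np.empty(n, np.int64)
    maxb = 2
    for f in range(F):
        if n_bins[f] > maxb:
            maxb = n_bins[f]
    cw = np.zeros(maxb)
    cs = np.zeros(maxb)
    keys = np.empty(F)

    np.random.seed(seed)

    stack_node = np.empty(max_nodes, np.int32)
    stack_start = np.empty(max_nodes, np.int64)
    stack_end = np.empty(max_nodes, np.int64)
    stack_w = np.empty(max_nodes)
    stack_s = np.empty(max_nodes)
    stack_q = np.empty(max_nodes)

    W0 = 0.0
    S0 = 0.0
    Q0 = 0.0
    for i in range(n):
        W0 += w[i]
        S0 += ysum[i]
        Q0 += ysq[i]

    node_count = 1
    stack_node[0] = 0
    stack_start[0] = 0
    stack_end[0] = n
    stack_w[0] = W0
    stack_s[0] = S0
    stack_q[0] = Q0
    top = 1
    while top > 0:
        top -= 1
        nd = stack_node[top]
        s = stack_start[top]
        e = stack_end[top]
        W = stack_w[top]
        S = stack_s[top]
        Q = stack_q[top]
        value[nd] = S / W
        nodew[nd] = W
        sse = Q - S * S / W
        if sse <= 1e-12 or W < 2.0 * min_leaf or node_count + 2 > max_nodes:
            continue

        # weighted sampling without replacement of the candidate set
        # (exponential-race keys: smallest -ln(u)/weight win)
        for f in range(F):
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            keys[f] = -np.log(u) / fweights[f]
        idx = np.argsort(keys)
        cand = np.sort(idx[:m_try])

        best_gain = _EPS_GAIN
        best_f = -1
        best_bin = -1
        for ci in range(cand.shape[0]):
            f = cand[ci]
            nb = n_bins[f]
            if nb < 2:
                continue
            for b in range(nb):
                cw[b] = 0.0
                cs[b] = 0.0
            for i in range(s, e):
                r = order[i]
                b = codes[r, f]
                cw[b] += w[r]
                cs[b] += ysum[r]
            Wl = 0.0
            Sl = 0.0
            for b in range(nb - 1):
                Wl += cw[b]
                Sl += cs[b]
                if Wl < min_leaf:
                    continue
                Wr = W - Wl
                if Wr < min_leaf:
                    break
                Sr = S - Sl
                g = Sl * Sl / Wl + Sr * Sr / Wr - S * S / W
                # strict > with features scanned in ascending index and
                # thresholds in ascending order: SSE ties break toward
                # the lower feature index, then the lower threshold
                if g > best_gain:
                    best_gain = g
                    best_f = f
                    best_bin = b
        if best_f < 0:
            continue

        nl = 0
        for i in range(s, e):
            r = order[i]
            if codes[r, best_f] <= best_bin:
                tmp[s + nl] = r
                nl += 1
        nr = 0
        for i in range(s, e):
            r = order[i]
            if codes[r, best_f] > best_bin:
                tmp[s + nl + nr] = r
                nr += 1
        for i in range(s, e):
            order[i] = tmp[i]
        mid = s + nl

        Wl = 0.0
        Sl = 0.0
        Ql = 0.0
        XL = 0.0
        for i in range(s, mid):
            r = order[i]
            Wl += w[r]
            Sl += ysum[r]
            Ql += ysq[r]
            XL += w[r] * xvals[r, best_f]
        XR = 0.0
        for i in range(mid, e):
            r = order[i]
            XR += w[r] * xvals[r, best_f]
        Wr = W - Wl
        Sr = S - Sl
        Qr = Q - Ql

        feat[nd] = best_f
        thr[nd] = thr_flat[thr_off[best_f] + best_bin]
        gain_a[nd] = best_gain
        wl_a[nd] = Wl
        wr_a[nd] = Wr
        myl_a[nd] = Sl / Wl
        myr_a[nd] = Sr / Wr
        mxl_a[nd] = XL / Wl
        mxr_a[nd] = XR / Wr

        lid = node_count
        rid = node_count + 1
        node_count += 2
        left[nd] = lid
        right[nd] = rid
        stack_node[top] = rid
        stack_start[top] = mid
        stack_end[top] = e
        stack_w[top] = Wr
        stack_s[top] = Sr
        stack_q[top] = Qr
        top += 1
        stack_node[top] = lid
        stack_start[top] = s
        stack_end[top] = mid
        stack_w[top] = Wl
        stack_s[top] = Sl
        stack_q[top] = Ql
        top += 1

    return (feat[:node_count].copy(), thr[:node_count].copy(),
            left[:node_count].copy(), right[:node_count].copy(),
            value[:node_count].copy(), nodew[:node_count].copy(),
            gain_a[:node_count].copy(), wl_a[:node_count].copy(),
            wr_a[:node_count].copy(), myl_a[:node_count].copy(),
            myr_a[:node_count].copy(), mxl_a[:node_count].copy(),
            mxr_a[:node_count].copy())


@njit(cache=True)
def _predict_tree(X, feat, thr, left, right, value, out):
    n = X.shape[0]
    for i in range(n):
        nd = 0
        while feat[nd] >= 0:
            if X[i, feat[nd]] <= thr[nd]:
                nd = left[nd]
            else:
                nd = right[nd]
        out[i] += value[nd]


def bin_features(X: np.ndarray, max_bins: int = 256):
    """Discretize columns of X for histogram split search.

    Returns ``(codes, n_bins, thr_flat, thr_off)``: integer bin codes per
    cell, the bin count per feature, and a flat array of candidate
    thresholds (midpoint between the largest value of a bin and the
    smallest value of the next) addressed by per-feature offsets.
    Features with fewer distinct values than ``max_bins`` are binned
    exactly on their distinct values.
    """
    n, F = X.shape
    codes = np.zeros((n, F), dtype=np.int32)
    n_bins = np.zeros(F, dtype=np.int32)
    thr_parts: list[np.ndarray] = []
    thr_off = np.zeros(F, dtype=np.int64)
    off = 0
    for f in range(F):
        v = X[:, f]
        uniq = np.unique(v)
        if uniq.size <= max_bins:
            codes[:, f] = np.searchsorted(uniq, v)
            thr = (uniq[:-1] + uniq[1:]) / 2.0
            nb = uniq.size
        else:
            qs = np.quantile(v, np.linspace(0.0, 1.0, max_bins + 1)[1:-1])
            edges = np.unique(qs)
            raw = np.searchsorted(edges, v, side="right")
            present, compact = np.unique(raw, return_inverse=True)
            nb = present.size
            codes[:, f] = compact
            binmax = np.full(nb, -np.inf)
            binmin = np.full(nb, np.inf)
            np.maximum.at(binmax, compact, v)
            np.minimum.at(binmin, compact, v)
            thr = (binmax[:-1] + binmin[1:]) / 2.0
        n_bins[f] = nb
        thr_off[f] = off
        thr_parts.append(thr)
        off += max(nb - 1, 0)
    thr_flat = (np.concatenate(thr_parts) if off > 0 else np.zeros(1))
    if thr_flat.size == 0:
        thr_flat = np.zeros(1)
    return codes, n_bins, thr_flat, thr_off


@dataclass
class Tree:
    """A fitted regression tree as flat node arrays.

    ``feature[i] < 0`` marks a leaf; internal nodes carry the split
    record consumed by the directionality stage: per-child weighted
    sample counts, mean outcomes, mean feature values and the SSE
    decrease of the split.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    node_weight: np.ndarray
    gain: np.ndarray
    weight_left: np.ndarray
    weight_right: np.ndarray
    mean_y_left: np.ndarray
    mean_y_right: np.ndarray
    mean_x_left: np.ndarray
    mean_x_right: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    @property
    def split_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.feature >= 0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros(X.shape[0])
        _predict_tree(np.ascontiguousarray(X, dtype=np.float64),
                      self.feature, self.threshold, self.left, self.right,
                      self.value, out)
        return out

    def feature_gains(self, n_features: int) -> np.ndarray:
        """Total SSE decrease attributed to each feature."""
        g = np.zeros(n_features)
        idx = self.split_nodes
        np.add.at(g, self.feature[idx], self.gain[idx])
        return g


def grow_tree(codes, xvals, w, ysum, ysq, n_bins, thr_flat, thr_off,
              fweights, m_try, min_leaf, seed) -> Tree:
    total_w = float(w.sum())
    max_leaves = max(1, min(int(total_w // min_leaf), xvals.shape[0]))
    max_nodes = 2 * max_leaves + 1
    arrays = _build_tree(codes, xvals, w, ysum, ysq, n_bins, thr_flat,
                         thr_off, fweights, m_try, min_leaf, seed, max_nodes)
    return Tree(*arrays)


def fit_tree(X, y, feature_weights=None, *, min_leaf: float = 1,
             mtry_fraction: float = 1.0, random_state: int = 0,
             max_bins: int = 256, sample_weight=None) -> Tree:
    """Fit a single weighted regression tree (CART, SSE criterion).

    With ``mtry_fraction=1`` every feature is a split candidate and the
    chosen split at every node is the exhaustive SSE minimizer over
    midpoints of adjacent distinct values (ties broken toward the lower
    feature index, then the lower threshold).  Leaves predict the
    weighted mean outcome of the samples that reached them, so for 0/1
    labels a leaf estimates a case proportion.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a nonempty 2-D array")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y length mismatch")
    n, F = X.shape
    if feature_weights is None:
        fw = np.full(F, 1.0 / F)
    else:
        fw = np.asarray(feature_weights, dtype=np.float64)
        if fw.sum() <= 0 or np.any(fw < 0):
            raise ValueError("feature weights must be nonnegative with positive sum")
        if np.all(fw == 0):
            raise ValueError("all features have zero weight")
    fw = np.where(fw <= 0, 1e-300, fw)
    if sample_weight is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weight, dtype=np.float64)
    codes, n_bins, thr_flat, thr_off = bin_features(X, max_bins)
    m_try = max(1, int(np.ceil(mtry_fraction * F)))
    m_try = min(m_try, F)
    return grow_tree(codes, X, w, w * y, w * y * y, n_bins, thr_flat,
                     thr_off, fw, m_try, float(min_leaf),
                     int(random_state) % (2**31), )
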