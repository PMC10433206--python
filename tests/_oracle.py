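"""Independent brute-force oracles used by the test suite.

The split oracle evaluates every (feature, midpoint-threshold) candidate
by directly computing the sum of squared deviations on each side — no
histograms, no incremental updates — so it shares no code path with the
tree implementation it checks.
"""

from __future__ import annotations

import numpy as np

TOL = 1e-9


def sse(y: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    if wsum <= 0:
        return 0.0
    mu = np.sum(w * y) / wsum
    return float(np.sum(w * (y - mu) ** 2))


def best_split_exhaustive(X, y, w, min_leaf):
    """Max SSE-decrease split by full enumeration.

    Returns (gain, feature, threshold) with ties broken toward the lower
    feature index then the lower threshold, or None if no candidate
    satisfies the leaf-size constraint with positive gain.
    """
    parent = sse(y, w)
    best = None
    n, F = X.shape
    for f in range(F):
        vals = np.unique(X[:, f])
        for thr in (vals[:-1] + vals[1:]) / 2.0:
            mask = X[:, f] <= thr
            wl, wr = w[mask].sum(), w[~mask].sum()
            if wl < min_leaf or wr < min_leaf:
                continue
            gain = parent - sse(y[mask], w[mask]) - sse(y[~mask], w[~mask])
            if gain <= TOL:
                continue
            if best is None or gain > best[0] + TOL:
                best = (gain, f, thr)
    return best


def assert_tree_matches_oracle(tree, X, y, w=None, min_leaf=1):
    """Walk a fitted tree; at every internal node the implemented split
    must achieve the exhaustive-search optimum (gain within TOL), and
    every leaf must be unimprovable or pure."""
    if w is None:
        w = np.ones(len(y))

    def walk(node, idx):
        Xs, ys, ws = X[idx], y[idx], w[idx]
        best = best_split_exhaustive(Xs, ys, ws, min_leaf)
        if tree.feature[node] < 0:
            assert best is None or sse(ys, ws) <= TOL, (
                f"leaf at node {node} but oracle finds gain {best}"
            )
            mu = np.sum(ws * ys) / ws.sum()
            assert abs(tree.value[node] - mu) < TOL
            return
        assert best is not None, f"split at node {node} but oracle finds none"
        f, thr = int(tree.feature[node]), float(tree.threshold[node])
        mask = Xs[:, f] <= thr
        wl, wr = ws[mask].sum(), ws[~mask].sum()
        assert wl >= min_leaf and wr >= min_leaf
        gain = sse(ys, ws) - sse(ys[mask], ws[mask]) - sse(ys[~mask], ws[~mask])
        assert gain >= best[0] - TOL, (
            f"node {node}: impl gain {gain} < oracle optimum {best[0]}"
        )
        walk(int(tree.left[node]), idx[mask])
        walk(int(tree.right[node]), idx[~mask])

    walk(0, np.arange(len(y)))
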