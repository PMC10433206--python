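"""Iterative random forest (iRF): forests of weighted regression trees.

The model is a sequence of random forests.  Iteration 1 samples split
candidates uniformly; each later iteration samples features with
probability proportional to the previous iteration's importances (plus a
small floor so no feature dies irreversibly).  Importance is the total
SSE decrease a feature contributes across all splits of all trees,
normalized to sum to one.  Trained on 0/1 case/control labels, every
leaf predicts the case proportion of the patients that reached it, so
forest scores live in [0, 1] and the final importance vector ranks
features by how strongly they drive that proportion.

Rows that share identical feature vectors (all patients of one ZIP
code) can be collapsed into weighted rows via the ``groups`` argument of
:meth:`IterativeRandomForestRegressor.fit`; the collapsed fit is
statistically identical (the bootstrap is still taken over patients, as
a multinomial over the (ZIP, label) cells) but runs on two orders of
magnitude fewer rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from ._tree import Tree, bin_features, grow_tree


class Forest:
    """A fitted forest: the mean of its trees' leaf-mean predictions."""

    def __init__(self, trees: list[Tree], n_features: int):
        self.trees = trees
        self.n_features = n_features

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        out = np.zeros(X.shape[0])
        for t in self.trees:
            out += t.predict(X)
        return out / len(self.trees)

    def raw_importance(self) -> np.ndarray:
        g = np.zeros(self.n_features)
        for t in self.trees:
            g += t.feature_gains(self.n_features)
        return g

    def importance(self) -> tuple[np.ndarray, bool]:
        """Normalized importance and a flag telling whether any split exists.

        A forest grown on constant labels makes no splits; its importance
        is the flagged zero vector rather than an arbitrary direction.
        """
        g = self.raw_importance()
        total = g.sum()
        if total <= 0:
            return np.zeros(self.n_features), False
        return g / total, True

    def iter_splits(self):
        """Yield (feature_idx, tree, node_idx) over all splits of all trees."""
        for t in self.trees:
            for nd in t.split_nodes:
                yield int(t.feature[nd]), t, int(nd)


class _FitData:
    """Pre-binned design shared by all trees and iterations of one fit.

    ``cell_row`` / ``cell_y`` / ``cell_count`` describe the patient-level
    multinomial cells used for bootstrapping: cell j holds ``cell_count``
    patients, all mapping to collapsed row ``cell_row`` with outcome
    ``cell_y``.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups, max_bins: int):
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if groups is None:
            self.xvals = X
            self.base_w = np.ones(X.shape[0])
            self.base_ysum = y.copy()
            self.base_ysq = y * y
            self.cell_row = np.arange(X.shape[0])
            self.cell_y = y.copy()
            self.cell_count = np.ones(X.shape[0])
        else:
            uniq, inv = np.unique(np.asarray(groups), return_inverse=True)
            if not np.all(np.isin(y, (0.0, 1.0))):
                raise ValueError("group-collapsed fitting requires 0/1 labels")
            n_g = uniq.size
            first = np.zeros(n_g, dtype=np.int64)
            first[inv[::-1]] = np.arange(X.shape[0] - 1, -1, -1)
            rows = X[first]
            if not np.array_equal(X, rows[inv]):
                raise ValueError(
                    "rows within a group must be identical to collapse by group"
                )
            c1 = np.bincount(inv, weights=y, minlength=n_g)
            cn = np.bincount(inv, minlength=n_g).astype(np.float64)
            self.xvals = np.ascontiguousarray(rows)
            self.base_w = cn
            self.base_ysum = c1
            self.base_ysq = c1  # y in {0,1}: sum of squares equals the sum
            self.cell_row = np.concatenate([np.arange(n_g), np.arange(n_g)])
            self.cell_y = np.concatenate([np.zeros(n_g), np.ones(n_g)])
            self.cell_count = np.concatenate([cn - c1, c1])
        keep = self.cell_count > 0
        self.cell_row = self.cell_row[keep]
        self.cell_y = self.cell_y[keep]
        self.cell_count = self.cell_count[keep]
        self.n_samples = int(self.cell_count.sum())
        self.n_rows = self.xvals.shape[0]
        self.codes, self.n_bins, self.thr_flat, self.thr_off = bin_features(
            self.xvals, max_bins
        )

    def bootstrap(self, rng: np.random.Generator):
        """Multinomial patient-level bootstrap, aggregated to rows."""
        k = rng.multinomial(self.n_samples, self.cell_count / self.n_samples)
        k = k.astype(np.float64)
        w = np.bincount(self.cell_row, weights=k, minlength=self.n_rows)
        ysum = np.bincount(self.cell_row, weights=k * self.cell_y,
                           minlength=self.n_rows)
        ysq = np.bincount(self.cell_row, weights=k * self.cell_y * self.cell_y,
                          minlength=self.n_rows)
        return w, ysum, ysq


def fit_forest(data: _FitData, feature_weights: np.ndarray, *, n_trees: int,
               min_leaf: float, m_try: int, bootstrap: bool,
               seed_seq: np.random.SeedSequence) -> Forest:
    fw = np.where(feature_weights <= 0, 1e-300, feature_weights)
    trees = []
    for child in seed_seq.spawn(n_trees):
        states = child.generate_state(2)
        if bootstrap:
            rng = np.random.default_rng(np.random.PCG64(child))
            w, ysum, ysq = data.bootstrap(rng)
        else:
            w, ysum, ysq = data.base_w, data.base_ysum, data.base_ysq
        tree = grow_tree(data.codes, data.xvals, w, ysum, ysq, data.n_bins,
                         data.thr_flat, data.thr_off, fw, m_try,
                         float(min_leaf), int(states[0] % (2**31)))
        trees.append(tree)
    return Forest(trees, data.xvals.shape[1])


class IterativeRandomForestRegressor(BaseEstimator, RegressorMixin):
    """Iterative random forest for case/control proportion regression.

    Parameters
    ----------
    n_trees : int, default 100
        Trees per forest (per iteration).  Desk-scale default; a
        national-scale run would use 1,000.
    min_leaf : float, default 50
        Minimum weighted sample (patient) count per leaf.  Desk-scale
        stand-in for the 1,000-patient leaves used at 400k-patient scale.
    mtry_fraction : float or None, default None
        Fraction of features drawn (weighted, without replacement) as
        split candidates at each node; the candidate set has size
        ``ceil(mtry_fraction * n_features)``.  ``None`` means
        ``sqrt(F)/F``.
    n_iterations : int, default 5
        Number of reweighting iterations.
    bootstrap : bool, default True
        Grow each tree on a patient-level bootstrap resample.
    epsilon : float or None, default None
        Floor added to importances before renormalizing into the next
        iteration's sampling weights; ``None`` means ``1/(100 F)``.
    max_bins : int, default 256
        Histogram resolution of the split search; exact below this many
        distinct values.
    random_state : int or None
        Seed for all forests, trees and bootstraps.

    Attributes
    ----------
    feature_names_in_ : ndarray of str (when fitted on a DataFrame)
    weights_ : ndarray (n_iterations, F)
        Candidate-sampling weight vectors; row 0 is uniform.
    importances_ : ndarray (n_iterations, F)
        Per-iteration normalized importance vectors.
    feature_importances_ : ndarray (F,)
        Final-iteration importance (the model's ranking signal).
    forests_ : list of Forest, one per iteration.
    ranking_ : list of feature names, descending final importance,
        ties broken by name.
    has_splits_ : bool
        False when no tree of the final forest made any split (constant
        labels); the importance vector is then the flagged zero vector.
    """

    def __init__(self, n_trees: int = 100, min_leaf: float = 50,
                 mtry_fraction: float | None = None, n_iterations: int = 5,
                 bootstrap: bool = True, epsilon: float | None = None,
                 max_bins: int = 256, random_state: int | None = None):
        self.n_trees = n_trees
        self.min_leaf = min_leaf
        self.mtry_fraction = mtry_fraction
        self.n_iterations = n_iterations
        self.bootstrap = bootstrap
        self.epsilon = epsilon
        self.max_bins = max_bins
        self.random_state = random_state

    def _validate(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.mtry_fraction is not None and not 0 < self.mtry_fraction <= 1:
            raise ValueError("mtry_fraction must be in (0, 1]")

    def fit(self, X, y, groups=None):
        """Fit the iterated forests.

        ``groups`` (e.g. the ZIP code of every patient) enables the
        collapsed weighted fit; rows within a group must be identical.
        """
        self._validate()
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xa = X.to_numpy(dtype=np.float64)
        else:
            Xa = np.asarray(X, dtype=np.float64)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(Xa.shape[1])], dtype=object
            )
        y = np.asarray(y, dtype=np.float64)
        if Xa.ndim != 2 or Xa.shape[0] == 0:
            raise ValueError("X must be a nonempty 2-D array")
        if y.shape[0] != Xa.shape[0]:
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = Xa.shape[1]
        F = Xa.shape[1]

        data = _FitData(Xa, y, groups, self.max_bins)
        frac = self.mtry_fraction if self.mtry_fraction is not None else np.sqrt(F) / F
        m_try = min(F, max(1, int(np.ceil(frac * F))))
        eps = self.epsilon if self.epsilon is not None else 1.0 / (100.0 * F)
        base = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        iter_seeds = base.spawn(self.n_iterations)

        weights = np.full(F, 1.0 / F)
        self.weights_ = np.empty((self.n_iterations, F))
        self.importances_ = np.empty((self.n_iterations, F))
        self.forests_ = []
        for t in range(self.n_iterations):
            self.weights_[t] = weights
            forest = fit_forest(
                data, weights, n_trees=self.n_trees, min_leaf=self.min_leaf,
                m_try=m_try, bootstrap=self.bootstrap, seed_seq=iter_seeds[t],
            )
            imp, has_splits = forest.importance()
            self.forests_.append(forest)
            self.importances_[t] = imp
            weights = imp + eps
            weights = weights / weights.sum()
        self.has_splits_ = has_splits
        order = np.lexsort((self.feature_names_in_, -self.importances_[-1]))
        self.ranking_ = [str(self.feature_names_in_[i]) for i in order]
        return self

    @property
    def feature_importances_(self) -> np.ndarray:
        return self.importances_[-1]

    @property
    def final_forest_(self) -> Forest:
        return self.forests_[-1]

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            return X.loc[:, list(self.feature_names_in_)].to_numpy(dtype=np.float64)
        Xa = np.asarray(X, dtype=np.float64)
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {Xa.shape[1]}"
            )
        return Xa

    def predict(self, X) -> np.ndarray:
        """Final-iteration forest score per row (a case proportion for
        0/1 training labels, hence bounded in [0, 1])."""
        return self.final_forest_.predict(self._as_matrix(X))

    def top_features(self, k: int) -> list[str]:
        """The k features with highest final importance (ties by name)."""
        return self.ranking_[:k]


def fit_irf(X, y, *, groups=None, **params) -> IterativeRandomForestRegressor:
    """Convenience wrapper: construct and fit an iterative forest."""
    return IterativeRandomForestRegressor(**params).fit(X, y, groups=groups)
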