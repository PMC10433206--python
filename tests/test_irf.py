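"""Iterated forest: weighting scheme, importance conservation, collapse
equivalence, prediction contracts."""

import numpy as np
import pandas as pd
import pytest

from georf import IterativeRandomForestRegressor, fit_irf


def _signal_data(n=1000, F=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, F))
    y = (X[:, 0] > np.median(X[:, 0])).astype(float)
    return X, y


class TestWeighting:
    def test_first_iteration_uniform(self):
        X, y = _signal_data(300, 6)
        m = fit_irf(X, y, n_trees=5, min_leaf=20, n_iterations=3, random_state=1)
        np.testing.assert_allclose(m.weights_[0], np.full(6, 1 / 6))

    def test_vectors_normalized_and_nonnegative(self):
        X, y = _signal_data(500, 8, seed=2)
        m = fit_irf(X, y, n_trees=10, min_leaf=20, n_iterations=4, random_state=2)
        for t in range(4):
            assert np.all(m.weights_[t] >= 0)
            assert np.all(m.importances_[t] >= 0)
            assert m.weights_[t].sum() == pytest.approx(1.0, abs=1e-9)
            assert m.importances_[t].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_iteration_is_plain_weighted_forest(self):
        X, y = _signal_data(300, 6, seed=3)
        m = fit_irf(X, y, n_trees=5, min_leaf=20, n_iterations=1, random_state=3)
        assert m.weights_.shape == (1, 6)
        np.testing.assert_allclose(m.weights_[0], np.full(6, 1 / 6))
        assert len(m.forests_) == 1

    def test_signal_weight_concentrates_over_iterations(self):
        # planted signal: its sampling weight at the final iteration
        # should not have decayed below the uniform start, across seeds
        wins = 0
        for seed in range(10):
            X, y = _signal_data(1000, 10, seed=seed)
            m = fit_irf(X, y, n_trees=30, min_leaf=25, n_iterations=5,
                        random_state=seed)
            wins += m.weights_[-1][0] >= m.weights_[0][0]
        assert wins >= 9

    def test_splitless_forest_flagged_zero(self):
        X = np.random.default_rng(0).normal(size=(100, 4))
        m = fit_irf(X, np.zeros(100), n_trees=5, min_leaf=10, random_state=0,
                    n_iterations=2)
        assert not m.has_splits_
        np.testing.assert_array_equal(m.feature_importances_, np.zeros(4))
        np.testing.assert_array_equal(m.predict(X), np.zeros(100))


class TestImportance:
    def test_signal_feature_ranks_first(self):
        X, y = _signal_data(2000, 10, seed=5)
        m = fit_irf(X, y, n_trees=30, min_leaf=50, n_iterations=3, random_state=5)
        assert int(np.argmax(m.feature_importances_)) == 0
        assert m.ranking_[0] == "x0"

    def test_ranking_ties_broken_by_name(self):
        X, y = _signal_data(200, 4, seed=6)
        m = fit_irf(X, y, n_trees=5, min_leaf=20, random_state=6, n_iterations=2)
        imp = dict(zip(m.feature_names_in_, m.feature_importances_))
        resorted = sorted(m.ranking_, key=lambda f: (-imp[f], f))
        assert resorted == m.ranking_


class TestPrediction:
    def test_scores_bounded(self, tiny_cohort):
        zips, patients, _ = tiny_cohort
        from georf.preprocess import build_design

        design = build_design(patients, zips)
        m = fit_irf(design.features, design.labels, groups=design.groups,
                    n_trees=10, min_leaf=30, n_iterations=2, random_state=1)
        s = m.predict(design.features)
        assert np.all(s >= 0) and np.all(s <= 1)

    def test_holdout_separation_with_strong_signal(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(3000, 6))
        p = 1 / (1 + np.exp(-(-2.0 + 2.0 * X[:, 0])))
        y = (rng.random(3000) < p).astype(float)
        m = fit_irf(X[:2000], y[:2000], n_trees=30, min_leaf=50, random_state=7,
                    n_iterations=3)
        s = m.predict(X[2000:])
        yt = y[2000:]
        assert s[yt == 1].mean() > s[yt == 0].mean()

    def test_missing_column_named(self):
        df = pd.DataFrame({"a": [0.0, 1, 2, 3], "b": [1.0, 0, 1, 0]})
        m = fit_irf(df, [0, 0, 1, 1], n_trees=2, min_leaf=1, n_iterations=1,
                    random_state=0)
        with pytest.raises(ValueError, match="b"):
            m.predict(df[["a"]])


class TestGroupCollapse:
    def test_collapsed_fit_equals_patient_level_fit(self):
        # deterministic settings (all features candidates, no bootstrap):
        # fitting on ZIP-collapsed weighted rows must reproduce the
        # patient-level tree exactly
        rng = np.random.default_rng(9)
        zip_X = rng.normal(size=(40, 4))
        assign = rng.integers(0, 40, size=600)
        X = zip_X[assign]
        y = (rng.random(600) < 1 / (1 + np.exp(-zip_X[assign, 0]))).astype(float)
        kw = dict(n_trees=3, min_leaf=25, mtry_fraction=1.0, bootstrap=False,
                  n_iterations=2, random_state=4)
        a = fit_irf(X, y, groups=assign, **kw)
        b = fit_irf(X, y, **kw)
        np.testing.assert_allclose(a.predict(X), b.predict(X), atol=1e-12)
        np.testing.assert_allclose(a.feature_importances_,
                                   b.feature_importances_, atol=1e-12)

    def test_collapse_rejects_heterogeneous_rows(self):
        X = np.arange(12.0).reshape(6, 2)
        with pytest.raises(ValueError, match="identical"):
            fit_irf(X, [0, 1, 0, 1, 0, 1], groups=[0, 0, 1, 1, 2, 2],
                    n_trees=2, min_leaf=1, n_iterations=1)


class TestDeterminism:
    def test_same_seed_identical_model(self):
        X, y = _signal_data(500, 6, seed=10)
        a = fit_irf(X, y, n_trees=10, min_leaf=20, n_iterations=3, random_state=5)
        b = fit_irf(X, y, n_trees=10, min_leaf=20, n_iterations=3, random_state=5)
        np.testing.assert_array_equal(a.importances_, b.importances_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_different_seed_differs(self):
        X, y = _signal_data(500, 6, seed=10)
        a = fit_irf(X, y, n_trees=10, min_leaf=20, n_iterations=2, random_state=5)
        b = fit_irf(X, y, n_trees=10, min_leaf=20, n_iterations=2, random_state=6)
        assert not np.array_equal(a.predict(X), b.predict(X))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            IterativeRandomForestRegressor(n_trees=0).fit(np.ones((5, 2)), np.ones(5))
        with pytest.raises(ValueError):
            IterativeRandomForestRegressor(mtry_fraction=1.5).fit(
                np.ones((5, 2)), np.ones(5)
            )
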