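"""PR-curve arithmetic, group-split integrity, CV behaviour under signal
and under the permutation null."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score

from georf.evaluation import (
    auprc,
    average_precision,
    cross_validate,
    group_shuffle_split,
    pr_curve,
    reduced_model,
)
from georf.io import RunConfig
from georf.preprocess import build_design


class TestPRCurve:
    def test_perfect_ranking(self):
        c = pr_curve([0.9, 0.8, 0.1], [1, 1, 0])
        assert auprc(c) == pytest.approx(1.0)
        assert any((r == 1.0) and (p == 1.0) for r, p in zip(c.recall, c.precision))

    def test_worst_ranking_of_two(self):
        # positives ranked last: AP = 1 * (1/2)
        c = pr_curve([1.0, 0.0], [0, 1])
        assert auprc(c) == pytest.approx(0.5)

    def test_all_positive_labels(self):
        c = pr_curve([0.3, 0.2, 0.9], [1, 1, 1])
        assert np.all(c.precision == 1.0)
        assert c.recall[-1] == 1.0

    def test_single_positive_ranked_first(self):
        scores = np.linspace(1, 0, 20)
        labels = np.zeros(20)
        labels[0] = 1
        assert average_precision(scores, labels) == pytest.approx(1.0)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([0.1, 0.2], [0, 0])

    def test_recall_monotone_ends_at_one(self, rng):
        scores = rng.random(500)
        labels = (rng.random(500) < 0.2).astype(int)
        c = pr_curve(scores, labels)
        assert np.all(np.diff(c.recall) >= 0)
        assert c.recall[-1] == pytest.approx(1.0)
        assert np.all((c.precision >= 0) & (c.precision <= 1))

    def test_matches_sklearn_average_precision(self, rng):
        for _ in range(5):
            scores = np.round(rng.random(300), 2)  # induce ties
            labels = (rng.random(300) < 0.15).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            assert average_precision(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.sampled_from(["affine", "exp", "cube"]))
    def test_invariant_under_monotone_transform(self, seed, kind):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.3).astype(int)
        labels[0] = 1
        f = {"affine": lambda s: 3 * s + 1, "exp": np.exp,
             "cube": lambda s: s**3}[kind]
        assert average_precision(scores, labels) == pytest.approx(
            average_precision(f(scores), labels)
        )

    def test_random_ranking_concentrates_at_prevalence(self, rng):
        p, n, reps = 0.1, 2000, 30
        vals = []
        for _ in range(reps):
            labels = (rng.random(n) < p).astype(int)
            vals.append(average_precision(rng.random(n), labels))
        assert abs(np.mean(vals) - p) < 4 * np.std(vals) / np.sqrt(reps) + 0.005


class TestGroupSplit:
    def test_disjoint_and_exhaustive(self, rng):
        groups = rng.integers(0, 40, size=1000)
        for tr, te in group_shuffle_split(groups, 0.2, n_repeats=20, seed=3):
            assert set(groups[tr]) & set(groups[te]) == set()
            assert len(tr) + len(te) == 1000

    def test_requested_repeats(self):
        splits = group_shuffle_split(np.arange(100) % 10, 0.2, n_repeats=5, seed=0)
        assert len(splits) == 5

    def test_equal_groups_exact_fraction(self):
        groups = np.repeat(np.arange(10), 7)
        for tr, te in group_shuffle_split(groups, 0.2, n_repeats=10, seed=1):
            assert len(np.unique(groups[te])) == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="single group"):
            group_shuffle_split(np.zeros(10), 0.2)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            group_shuffle_split(np.arange(10), 1.5)


@pytest.fixture(scope="module")
def small_design():
    from georf.synthetic import (
        CausalFeature, SyntheticConfig, generate_patients, generate_zip_features,
    )

    cfg = SyntheticConfig(
        n_zips=200, n_demo_features=20, n_patients=6000,
        prevalence_by_age={"under_60": 0.15, "60_plus": 0.15},
        causal_features=(
            CausalFeature("acs_share_0000", 1.2),
            CausalFeature("acs_share_0001", -1.2),
        ),
        corr_groups=(), seed=21,
    )
    zips = generate_zip_features(cfg)
    patients, _ = generate_patients(zips, cfg)
    return build_design(patients, zips)


class TestCrossValidate:
    def test_signal_beats_baseline(self, small_design):
        cfg = RunConfig(n_trees=20, min_leaf=30, n_iterations=2, n_repeats=5,
                        seed=5)
        res = cross_validate(small_design, cfg)
        above = sum(a > b for a, b in zip(res.auprcs, res.baselines))
        assert above >= 4
        assert res.mean_auprc > res.baseline

    def test_permuted_labels_fall_to_baseline(self, small_design):
        rng = np.random.default_rng(0)
        from dataclasses import replace
        from georf.preprocess import DesignMatrix

        perm = DesignMatrix(
            small_design.patient_ids,
            rng.permutation(small_design.labels),
            small_design.features,
            small_design.groups,
        )
        cfg = RunConfig(n_trees=10, min_leaf=50, n_iterations=2, n_repeats=5,
                        seed=9)
        res = cross_validate(perm, cfg)
        spread = np.std(res.auprcs) + 0.01
        assert abs(res.mean_auprc - res.baseline) < 4 * spread

    def test_deterministic(self, small_design):
        cfg = RunConfig(n_trees=5, min_leaf=50, n_iterations=2, n_repeats=3,
                        seed=13)
        a = cross_validate(small_design, cfg)
        b = cross_validate(small_design, cfg)
        assert a.auprcs == b.auprcs and a.baselines == b.baselines


class TestReducedModel:
    def test_reduced_set_contract(self, small_design):
        cfg = RunConfig(n_trees=5, min_leaf=50, n_iterations=2, n_repeats=2,
                        seed=3)
        res = reduced_model(small_design, cfg)
        assert 20 <= len(res.reduced_features) <= 22
        assert "firearms_per_10k" in res.reduced_features
        assert "alcohol_per_10k" in res.reduced_features
        assert set(res.reduced_features) <= set(small_design.feature_names)
        assert res.cv_all.model_tag == "all_features"
        assert res.cv_reduced.model_tag == "reduced"
        assert res.cv_all.n_repeats == res.cv_reduced.n_repeats == 2

    def test_vendors_in_top_k_shrink_the_union(self, small_design):
        cfg = RunConfig(n_trees=5, min_leaf=50, n_iterations=2, n_repeats=2,
                        seed=3, top_k=len(small_design.feature_names))
        res = reduced_model(small_design, cfg)
        # vendors are already inside the top-k: union adds nothing
        assert len(res.reduced_features) == len(small_design.feature_names)

    def test_too_few_features_rejected(self, small_design):
        cfg = RunConfig(n_trees=2, min_leaf=50, n_iterations=1, n_repeats=2,
                        seed=3)
        narrow = small_design.subset_features(
            ["firearms_per_10k", "alcohol_per_10k", "acs_share_0000"]
        )
        with pytest.raises(ValueError, match="at least"):
            reduced_model(narrow, cfg)

    def test_missing_forced_feature_rejected(self, small_design):
        cfg = RunConfig(n_trees=2, min_leaf=50, n_iterations=1, n_repeats=2,
                        seed=3, forced_features=("not_a_column",))
        with pytest.raises(ValueError, match="not_a_column"):
            reduced_model(small_design, cfg)
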