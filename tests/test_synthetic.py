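"""The generator must honor its structural contracts and plant what it
claims: block shapes, correlation targets, label mechanism, age shape."""

import numpy as np
import pandas as pd
import pytest

from georf.synthetic import (
    AGE_CUTOFF,
    CausalFeature,
    CorrGroup,
    SyntheticConfig,
    corr_group_columns,
    generate_patients,
    generate_zip_features,
    monthly_climate_columns,
    planted_dependency_matrix,
    static_climate_columns,
)


class TestZipFeatures:
    def test_block_structure(self, tiny_config, tiny_cohort):
        zips, _, _ = tiny_cohort
        monthly = [c for c in zips.columns if c.startswith("clim_") and "_static_" not in c]
        static = [c for c in zips.columns if c.startswith("clim_static_")]
        assert len(monthly) == 144  # 12 measurement types x 12 months
        assert len(static) == 30
        shares = [c for c in zips.columns if c.startswith("acs_share_")]
        assert len(shares) == tiny_config.n_demo_features
        assert {"population_density", "water_land_ratio",
                "firearms_per_10k", "alcohol_per_10k"} <= set(zips.columns)
        assert zips.shape[1] == 1 + 144 + 30 + tiny_config.n_demo_features + 2 + 2

    def test_value_contracts(self, tiny_cohort):
        zips, _, _ = tiny_cohort
        assert not zips.isna().any().any()
        assert zips["zip_id"].is_unique
        shares = zips[[c for c in zips.columns if c.startswith("acs_share_")]]
        assert ((shares >= 0) & (shares <= 1)).all().all()
        assert (zips["firearms_per_10k"] >= 0).all()
        assert (zips["alcohol_per_10k"] >= 0).all()

    def test_planted_pair_correlation(self):
        cfg = SyntheticConfig(n_zips=2000, n_demo_features=2, n_patients=10,
                              causal_features=(), corr_groups=(CorrGroup(2, 0.95),),
                              seed=3)
        zips = generate_zip_features(cfg)
        (members,) = corr_group_columns(cfg)
        r = np.corrcoef(zips[members[0]], zips[members[1]])[0, 1]
        assert abs(r) >= 0.90

    def test_all_group_pairs_reach_target(self):
        cfg = SyntheticConfig(n_zips=1000, n_demo_features=2, n_patients=10,
                              causal_features=(),
                              corr_groups=(CorrGroup(4, 0.92),), seed=5)
        zips = generate_zip_features(cfg)
        (members,) = corr_group_columns(cfg)
        R = np.corrcoef(zips[list(members)].to_numpy(), rowvar=False)
        off = np.abs(R[np.triu_indices(4, 1)])
        assert (off >= 0.92).all()

    def test_determinism(self, tiny_config):
        a = generate_zip_features(tiny_config)
        b = generate_zip_features(tiny_config)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_zips": 1},
            {"corr_groups": ((1, 0.95),)},
            {"corr_groups": ((2, 0.8),)},
            {"prevalence_by_age": {"under_60": 0.0, "60_plus": 0.5}},
            {"prevalence_by_age": {"under_60": 0.1}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(n_demo_features=2, causal_features=(), **kwargs)


class TestPatients:
    def test_determinism(self, tiny_config, tiny_cohort):
        zips, patients, _ = tiny_cohort
        again, _ = generate_patients(zips, tiny_config)
        pd.testing.assert_frame_equal(patients, again)

    def test_contracts(self, tiny_cohort):
        zips, patients, _ = tiny_cohort
        assert patients["label"].isin((0, 1)).all()
        assert (patients["age"] >= 18).all()
        assert patients["zip_id"].isin(zips["zip_id"]).all()
        assert patients["patient_id"].is_unique

    def test_missing_causal_feature_named(self, tiny_cohort):
        zips, _, _ = tiny_cohort
        cfg = SyntheticConfig(
            n_zips=150, n_demo_features=8, n_patients=100,
            causal_features=(CausalFeature("no_such_column", 1.0),),
            corr_groups=(), seed=0,
        )
        with pytest.raises(ValueError, match="no_such_column"):
            generate_patients(zips, cfg)

    def test_null_model_hits_target_prevalence(self):
        # all coefficients zero: case fraction must sit within 3 binomial
        # standard errors of the configured 0.035 at n = 50,000
        p = 0.035
        cfg = SyntheticConfig(
            n_zips=500, n_demo_features=2, n_patients=50_000,
            prevalence_by_age={"under_60": p, "60_plus": p},
            causal_features=(), corr_groups=(), seed=11,
        )
        zips = generate_zip_features(cfg)
        patients, truth = generate_patients(zips, cfg)
        se = np.sqrt(p * (1 - p) / len(patients))
        assert abs(patients["label"].mean() - p) < 3 * se
        from scipy.special import logit

        assert truth.intercepts["under_60"] == pytest.approx(float(logit(p)))

    def test_null_feature_has_no_gradient(self):
        # a zero-coefficient feature: case rates in its top and bottom
        # ZIP tertiles differ by less than 3 two-proportion standard
        # errors (no other ZIP-level effect, so labels are independent
        # of ZIP and the binomial error model applies)
        cfg = SyntheticConfig(
            n_zips=500, n_demo_features=4, n_patients=50_000,
            causal_features=(), corr_groups=(), seed=13,
        )
        zips = generate_zip_features(cfg)
        patients, _ = generate_patients(zips, cfg)
        x = zips.set_index("zip_id")["acs_share_0003"]
        vals = x.loc[patients["zip_id"]].to_numpy()
        lo, hi = np.quantile(vals, [1 / 3, 2 / 3])
        top = patients["label"].to_numpy()[vals >= hi]
        bot = patients["label"].to_numpy()[vals <= lo]
        p1, p2 = top.mean(), bot.mean()
        pool = np.concatenate([top, bot]).mean()
        se = np.sqrt(pool * (1 - pool) * (1 / len(top) + 1 / len(bot)))
        assert abs(p1 - p2) < 3 * se

    def test_monotone_response_to_planted_risk_feature(self):
        cfg = SyntheticConfig(
            n_zips=1000, n_demo_features=4, n_patients=50_000,
            causal_features=(CausalFeature("acs_share_0000", 1.0),),
            corr_groups=(), seed=17,
        )
        zips = generate_zip_features(cfg)
        patients, _ = generate_patients(zips, cfg)
        x = zips.set_index("zip_id")["acs_share_0000"]
        vals = x.loc[patients["zip_id"]].to_numpy()
        y = patients["label"].to_numpy()
        qs = np.quantile(vals, np.linspace(0, 1, 6))
        rates, ns = [], []
        for a, b in zip(qs[:-1], qs[1:]):
            m = (vals >= a) & (vals <= b)
            rates.append(y[m].mean())
            ns.append(m.sum())
        for i in range(4):
            se = np.sqrt(rates[i] * (1 - rates[i]) / ns[i]
                         + rates[i + 1] * (1 - rates[i + 1]) / ns[i + 1])
            assert rates[i + 1] >= rates[i] - 3 * se
        assert rates[-1] > rates[0]

    def test_age_shape(self, tiny_config):
        cfg = SyntheticConfig(n_zips=300, n_demo_features=2, n_patients=40_000,
                              causal_features=(), corr_groups=(), seed=19)
        zips = generate_zip_features(cfg)
        patients, _ = generate_patients(zips, cfg)
        ages = patients["age"].to_numpy()
        assert ages.min() >= 18 and ages.max() <= 95
        # mass peaks near the cutoff and declines steeply above it
        near = ((ages >= AGE_CUTOFF) & (ages < AGE_CUTOFF + 7)).mean()
        far = ((ages >= AGE_CUTOFF + 7) & (ages < AGE_CUTOFF + 14)).mean()
        assert near > far > 0
        assert 0.35 < (ages >= AGE_CUTOFF).mean() < 0.75


class TestDependencyMatrix:
    def test_structure_and_bounds(self):
        df, deps = planted_dependency_matrix(seed=1)
        assert df.shape == (1000, 51)
        assert len(deps) == 15  # 5 dependencies x 3 parents
        M = df.drop(columns="zip_id").to_numpy()
        R = np.corrcoef(M, rowvar=False)
        np.fill_diagonal(R, 0.0)
        assert np.abs(R).max() < 0.90  # survives pruning intact
        # parent-target correlations are materially present
        for s, t in deps:
            assert abs(np.corrcoef(df[s], df[t])[0, 1]) > 0.4

    def test_determinism(self):
        a, _ = planted_dependency_matrix(seed=2)
        b, _ = planted_dependency_matrix(seed=2)
        pd.testing.assert_frame_equal(a, b)
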