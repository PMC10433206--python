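import numpy as np
import pytest

from georf.io import RunConfig
from georf.synthetic import (
    CausalFeature,
    CorrGroup,
    SyntheticConfig,
    generate_patients,
    generate_zip_features,
)


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """A desk-top cohort small enough for unit tests."""
    return SyntheticConfig(
        n_zips=150,
        n_demo_features=8,
        n_patients=2500,
        causal_features=(
            CausalFeature("acs_share_0000", -1.0, "both"),
            CausalFeature("acs_share_0001", +1.0, "both"),
            CausalFeature("firearms_per_10k", +0.6, "both"),
        ),
        corr_groups=(CorrGroup(2, 0.95),),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    zips = generate_zip_features(tiny_config)
    patients, truth = generate_patients(zips, tiny_config)
    return zips, patients, truth


@pytest.fixture()
def fast_run_config() -> RunConfig:
    """Forest settings scaled down for quick unit runs."""
    return RunConfig(
        n_trees=10, min_leaf=20, n_iterations=2, n_repeats=2, seed=7,
        loop_n_trees=4, loop_n_iterations=2, loop_min_leaf=20,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
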