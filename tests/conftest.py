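import dataclasses

import numpy as np
import pytest

import matgaze as mg


@pytest.fixture(scope="session")
def six_group_config():
    """Single 6-year-old-like group, 12 participants: small but realistic."""
    cfg = mg.default_config(n_per_group=12, seed=7)
    return dataclasses.replace(cfg, groups=(cfg.groups[0],))


@pytest.fixture(scope="session")
def small_cohort(six_group_config):
    return mg.simulate_cohort(six_group_config, seed=7)


@pytest.fixture(scope="session")
def small_cohort_light(six_group_config):
    return mg.simulate_cohort(six_group_config, seed=7, light=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
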