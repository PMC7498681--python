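"""Shared fixtures: full-size ecosystem simulations, computed once per session."""

import numpy as np
import pytest

from phagecoi import gut_config, marine_config, simulate_ecosystem

FULL_N = 100_000
MARINE_SEED = 7
GUT_SEED = 11


@pytest.fixture(scope="session")
def marine_cfg():
    return marine_config()


@pytest.fixture(scope="session")
def gut_cfg():
    return gut_config()


@pytest.fixture(scope="session")
def marine_sim(marine_cfg):
    return simulate_ecosystem(marine_cfg, FULL_N, master_seed=MARINE_SEED)


@pytest.fixture(scope="session")
def gut_sim(gut_cfg):
    return simulate_ecosystem(gut_cfg, FULL_N, master_seed=GUT_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(20200915 % (2**16))
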