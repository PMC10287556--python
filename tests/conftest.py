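import numpy as np
import pytest

from envlink import SimConfig, simulate_views


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-mode cohort shared across read-only tests."""
    cfg = SimConfig(n_participants=4000, seed=11, n_snps=40)
    dataset, truth = simulate_views(cfg)
    return cfg, dataset, truth


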