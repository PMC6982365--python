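import numpy as np
import pytest

import pleiomed as pm


@pytest.fixture(scope="session")
def paper_cohort():
    """One paper-scale cohort (~5.8k individuals) shared across tests."""
    cfg = pm.make_scenario("paper_like", seed=42)
    df, truth = pm.simulate_cohort(cfg)
    return cfg, df, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A smaller cohort (~1.6k individuals) for cheaper fits."""
    cfg = pm.make_scenario("paper_like", seed=7, n_families=800)
    df, truth = pm.simulate_cohort(cfg)
    return cfg, df, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
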