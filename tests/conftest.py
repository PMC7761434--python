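import numpy as np
import pytest

from wcmfe import FEParams, SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return FEParams()  # m=2, n=2, r=0.15


@pytest.fixture(scope="session")
def small_dataset():
    """A small but informative synthetic dataset (defaults, fewer trials)."""
    cfg = SimConfig(n_trials_per_class=10, seed=0)
    trials, labels = generate_dataset(cfg)
    return cfg, trials, labels
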