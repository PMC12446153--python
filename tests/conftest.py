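import numpy as np
import pytest

import cse_multiverse as cm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flanker_params():
    return cm.default_params("flanker")


@pytest.fixture(scope="session")
def prime_probe_params():
    return cm.default_params("prime_probe")


@pytest.fixture(scope="session")
def small_trials():
    """One small end-to-end dataset (8 participants x 4 cells x 50 trials)."""
    return cm.generate_dataset(cm.default_params("prime_probe"), 8, 50, master_seed=2024)


@pytest.fixture(scope="session")
def small_correct(small_trials):
    return cm.exclude_errors(small_trials)
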