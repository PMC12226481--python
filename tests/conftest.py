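import numpy as np
import pytest

from fnssir.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_session():
    """One full-size synthetic session (126 trials, 42 per class, 100 Hz)."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def tiny_session():
    """A small, fast session for plumbing tests (12 trials)."""
    return generate_dataset(SyntheticConfig(n_trials_per_class=4, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
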