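import numpy as np
import pytest

from goaldyn.fixtures import FixtureConfig, generate_dataset
from goaldyn.game import GameConfig


@pytest.fixture(scope="session")
def game():
    return GameConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """A small labelled fixture dataset shared across tests."""
    cfg = FixtureConfig(n_trials=40, max_steps=150, seed=11)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
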