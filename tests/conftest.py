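import numpy as np
import pytest

from geomintruder.geometry import (
    DeckConfig,
    build_deck,
    load_base_shapes,
    sequence_trials,
)


@pytest.fixture(scope="session")
def families():
    return load_base_shapes()


@pytest.fixture(scope="session")
def fam_map(families):
    return {f.name: f for f in families}


@pytest.fixture(scope="session")
def deck_config():
    return DeckConfig(rng_seed=7)


@pytest.fixture(scope="session")
def deck(families, deck_config):
    return build_deck(families, deck_config)


@pytest.fixture(scope="session")
def sequence(deck, deck_config):
    return sequence_trials(deck, deck_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
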