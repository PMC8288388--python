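import numpy as np
import pytest

from spellbreak import p300, synth


@pytest.fixture(scope="session")
def small_p300_config():
    """A desk-scale P300 subject: full schedule structure, fewer trials."""
    return synth.P300SimConfig(n_train_chars=10, n_test_chars=8, seed=7)


@pytest.fixture(scope="session")
def small_p300_train(small_p300_config):
    return synth.make_p300_session(small_p300_config, "train")


@pytest.fixture(scope="session")
def small_p300_test(small_p300_config):
    return synth.make_p300_session(small_p300_config, "test")


@pytest.fixture(scope="session")
def small_p300_model(small_p300_train):
    return p300.train(p300.P300ModelConfig(), small_p300_train)


@pytest.fixture(scope="session")
def ssvep_session():
    """Two-block SSVEP session at default study conditions."""
    return synth.make_ssvep_session(synth.SSVEPSimConfig(seed=11, n_blocks=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
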