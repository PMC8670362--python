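import numpy as np
import pytest

from petmc import phantom, preprocess


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def desk_config():
    return phantom.PhantomConfig(noise_scale=0.0)


@pytest.fixture(scope="session")
def small_config():
    """A 24x24x12 phantom with halved geometry; fast enough for loops."""
    return phantom.small_phantom_config(noise_scale=0.0)


@pytest.fixture(scope="session")
def noiseless_seq(desk_config):
    seq, labels, n_eq = phantom.generate_phantom(desk_config, 0)
    return seq, labels, n_eq


@pytest.fixture(scope="session")
def normalized_seq(noiseless_seq):
    seq, labels, n_eq = noiseless_seq
    norm, _ = preprocess.temporal_normalize(seq, n_eq)
    return norm


@pytest.fixture(scope="session")
def small_seq(small_config):
    seq, labels, n_eq = phantom.generate_phantom(small_config, 3)
    return seq, labels, n_eq
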