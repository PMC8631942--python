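import numpy as np
import pytest

from shpkit.spr import load_reference_affinities
from shpkit.synthetic import NoiseModel, SimConfig


@pytest.fixture(scope="session")
def affinity_table():
    return load_reference_affinities()


@pytest.fixture
def config():
    return SimConfig(seed=7)


@pytest.fixture
def noisy_config():
    return SimConfig(seed=7, noise=NoiseModel(gaussian_sd=2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
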