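import numpy as np
import pytest

from bm4dpar import NoiseModel, Volume, add_gaussian_noise, make_modified_profile, make_phantom


@pytest.fixture(scope="session")
def profile():
    return make_modified_profile()


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom((32, 32, 32), kind="ellipsoids", seed=1)


@pytest.fixture(scope="session")
def noisy32(phantom32):
    return add_gaussian_noise(phantom32.volume, NoiseModel(sigma=0.1), seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_volume(rng):
    return Volume(rng.uniform(0.0, 1.0, (16, 16, 16)))
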