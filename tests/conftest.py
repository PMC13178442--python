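import numpy as np
import pytest

import countfm as cf


@pytest.fixture(scope="session")
def point_mass_pair():
    return cf.make_fixture_pairs("point_mass")


@pytest.fixture(scope="session")
def random_small_pair():
    return cf.make_fixture_pairs("random_small", seed=11)


@pytest.fixture(scope="session")
def small_model():
    return cf.init_rate_model(2, cf.ArchConfig(hidden=(16,)), seed=3)


@pytest.fixture(scope="session")
def cond_model():
    return cf.init_rate_model(
        2, cf.ArchConfig(hidden=(16,)), cond_spec=("real", 1), seed=4
    )


class ZeroRates:
    """Model stub with no dynamics: the sampler must return x_init."""

    def rates(self, x, t, y=None):
        z = np.zeros(np.asarray(x).shape, dtype=float)
        return cf.RatePair(z, z.copy())


@pytest.fixture()
def zero_rate_model():
    return ZeroRates()
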