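import numpy as np
import pytest

from segsense.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom32():
    """Small phantom shared by read-only tests."""
    return make_phantom(PhantomSpec(shape=(32, 32, 32), rng_seed=7))


@pytest.fixture(scope="session")
def phantom48():
    return make_phantom(PhantomSpec(shape=(48, 48, 48), rng_seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
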