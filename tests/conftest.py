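import numpy as np
import pytest

from emseg.image_io import RunConfig
from emseg.phantom import PhantomSpec, make_session


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=(24, 24, 24), seed=7)


@pytest.fixture(scope="session")
def clean_phantom(small_spec):
    """Noise-free, bias-free 24³ session with exact priors."""
    return make_session(small_spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """32³ session with rf=20 bias, 3% noise and slightly blurred priors."""
    return make_session(PhantomSpec(shape=(32, 32, 32), pn=3.0, rf=20.0,
                                    prior_blur=1.0, seed=11))


@pytest.fixture
def fast_config():
    return RunConfig(outer_max_iter=2, em_max_iter=10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
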