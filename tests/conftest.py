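import numpy as np
import pytest

from octdr import phantom


@pytest.fixture(scope="session")
def default_params() -> phantom.PhantomParams:
    return phantom.PhantomParams()


@pytest.fixture(scope="session")
def healthy_volume(default_params):
    """One default-size healthy phantom, reused across read-only tests."""
    return phantom.generate_phantom_volume("healthy", default_params, seed=7)


@pytest.fixture(scope="session")
def dr_volume(default_params):
    return phantom.generate_phantom_volume("DR", default_params, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
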