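import numpy as np
import pytest

from limbalign import phantom


@pytest.fixture(scope="session")
def standard_case():
    """One deterministic physiologic phantom shared across tests."""
    return phantom.generate_phantom(phantom.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def left_case():
    return phantom.generate_phantom(phantom.PhantomSpec(side="left", seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
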