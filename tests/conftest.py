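import numpy as np
import pytest

from dtialps.gradients import default_gradient_table
from dtialps.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def gtab():
    return default_gradient_table()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom without noise, shared across tests."""
    spec = PhantomSpec(snr=float("inf"))
    dwi, gtab, labels, truth = make_phantom(spec)
    return spec, dwi, gtab, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)
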