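import numpy as np
import pytest

from debipm.core import DEBParams, default_grid


@pytest.fixture(scope="session")
def params():
    """Published bulb mite life-history parameters."""
    return DEBParams()


@pytest.fixture(scope="session")
def grid(params):
    """The standard 200-bin length mesh over [0.9 L_b, L_m]."""
    return default_grid(params)


@pytest.fixture(scope="session")
def coarse_grid(params):
    """A 10-bin mesh for oracle comparisons that enumerate entries."""
    return default_grid(params, n_bins=10)


@pytest.fixture
def rng():
    return np.random.default_rng(20180617)
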