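import numpy as np
import pytest

from itsmeta import ITSTrueParams, generate_its_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ar_series(rng):
    """A moderately autocorrelated series of typical study length."""
    truth = ITSTrueParams(beta0=0.5, beta1=0.02, beta2=1.0, beta3=0.1,
                          rho=0.4)
    return generate_its_series(truth, T=48, TI=25, rng=rng)
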