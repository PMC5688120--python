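import numpy as np
import pytest
from hypothesis import settings

from kinasemsm import synthetic as syn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def btk_chains():
    """Calibrated deprotonated (ASP) and protonated (ASH) fixture chains."""
    return syn.calibrate_btk_chains()


@pytest.fixture(scope="session")
def asp_chain(btk_chains):
    return btk_chains[0]


@pytest.fixture(scope="session")
def ash_chain(btk_chains):
    return btk_chains[1]


@pytest.fixture(scope="session")
def three_state_chain():
    """Small hand-built detailed-balance chain for estimator tests."""
    g = np.array([0.0, 0.5, 1.0])
    b = np.array([
        [np.inf, 1.5, 2.0],
        [1.5, np.inf, 1.8],
        [2.0, 1.8, np.inf],
    ])
    return syn.build_kinase_chain(g, b, dt=1.0, temperature=300.0, rate_scale=0.3)
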