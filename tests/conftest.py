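import numpy as np
import pytest

from polyarch import synthdata as sd


@pytest.fixture(scope="session")
def hwe_panel():
    """2000 Hardy-Weinberg founders at 500 loci (session-wide, read-only)."""
    return sd.simulate_founders(2000, 500, ("uniform", 0.05, 0.5), seed=11)


@pytest.fixture(scope="session")
def small_selfing_study():
    """A 15-family selfing program to S5 with heights at h2 = 0.5."""
    founders = sd.simulate_founders(40, 200, ("uniform", 0.1, 0.5), seed=5)
    return sd.simulate_selfing_program(founders, generations=5, h2_height=0.5, seed=6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
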