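import numpy as np
import pytest

from postictal import SimConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study (16 subjects x 4 sessions) for join/scoring tests."""
    return simulate_study(SimConfig(n_subjects=16, sessions_per_subject=4.0,
                                    seed=99))
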