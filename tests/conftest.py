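import numpy as np
import pytest

from alphastates import EmissionParams, MarkovParams, simulate_state_sequence

HEALTHY_S1 = MarkovParams(p_low_to_high=0.53, p_high_to_low=0.25)


@pytest.fixture(scope="session")
def healthy_s1_params() -> MarkovParams:
    return HEALTHY_S1


@pytest.fixture(scope="session")
def long_healthy_sequence() -> np.ndarray:
    """100k-epoch chain at the healthy session-1 rates, shared across tests."""
    return simulate_state_sequence(HEALTHY_S1, 100_000, seed=12345)


@pytest.fixture(scope="session")
def quiet_emission() -> EmissionParams:
    """Well-separated state amplitudes, low broadband noise."""
    return EmissionParams(amp_high=20.0, amp_low=5.0, pink_noise_sd=1.0,
                          white_noise_sd=0.5, sampling_rate=1000)
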