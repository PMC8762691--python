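import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort():
    """A well-behaved simulated cohort reused across read-only tests."""
    from serialdep.observers import ObserverParams, simulate_experiment

    params = ObserverParams(
        dog_amplitude_deg=2.5,
        dog_width=0.05,
        global_bias_deg=1.0,
        lapse_rate=0.01,
        conditioning="previous_response",
        seed=123,
    )
    return simulate_experiment(params, n_participants=6, n_trials=400)


@pytest.fixture()
def tiny_table():
    """Hand-written two-participant table for exact-value tests."""
    return pd.DataFrame(
        {
            "participant_id": ["a"] * 4 + ["b"] * 4,
            "trial_index": [1, 2, 3, 4] * 2,
            "orientation_deg": [10.0, 30.0, 170.0, 10.0, 100.0, 80.0, 5.0, 175.0],
            "noise_level": ["low", "high", "low", "high"] * 2,
            "response_deg": [10.0, 35.0, 5.0, 175.0, 100.0, 75.0, 10.0, 170.0],
        }
    )
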