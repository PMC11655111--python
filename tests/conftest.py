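import numpy as np
import pytest

from apneakit.synthetic import EventSpec, SubjectProfile, generate_recording


@pytest.fixture(scope="session")
def profile() -> SubjectProfile:
    return SubjectProfile("S0", baseline_spo2=96.5, resp_rate=0.25,
                          heart_rate=65.0, snore_propensity=0.6, seed=5)


@pytest.fixture(scope="session")
def short_recording(profile):
    """One deterministic half-hour recording with a moderate event load."""
    return generate_recording(
        profile, 0.5, event_rate_per_h=20,
        class_mix={"OSA": 0.4, "CSA": 0.2, "MSA": 0.2, "HYP": 0.2},
        wake_fraction=0.1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def one_event(cls: str, onset: float = 600.0, duration: float = 30.0) -> EventSpec:
    return EventSpec(cls, onset, duration)
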