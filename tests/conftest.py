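import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")

from whiskerkin import AngleTrace, Config


@pytest.fixture
def cfg() -> Config:
    return Config()


def make_trace(angle, onset=500.0, duration=1000.0, dt=2.0, subject="s1", day=0.0,
               trial=0):
    return AngleTrace(
        subject_id=subject, day=day, trial_index=trial,
        stim_duration_ms=duration, stim_onset_ms=onset,
        angle_deg=np.asarray(angle, dtype=float), sample_period_ms=dt,
    )


@pytest.fixture
def flat_trace():
    return make_trace(np.full(1500, 5.0))
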