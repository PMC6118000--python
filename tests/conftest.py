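import numpy as np
import pytest

from ecgposture.synthetic import (
    SubjectProfile,
    make_position_schedule,
    synthesize_recording,
)


@pytest.fixture(scope="session")
def clean_recording():
    """10-minute zero-noise recording visiting all four positions."""
    profile = SubjectProfile(subject_id="S01", seed=3).noiseless()
    schedule = make_position_schedule(20, mean_run=5, seed=1)
    return synthesize_recording(profile, schedule)


@pytest.fixture(scope="session")
def noisy_recording():
    """Same subject/schedule with the default noise model switched on."""
    profile = SubjectProfile(subject_id="S01", seed=3)
    schedule = make_position_schedule(20, mean_run=5, seed=1)
    return synthesize_recording(profile, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
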