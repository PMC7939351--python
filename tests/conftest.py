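import numpy as np
import pytest
from hypothesis import settings

from isoglyco import ClampSimParams, SubjectRecord, simulate_clamp

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def subject() -> SubjectRecord:
    """A reference obese male subject (100 kg, 58 kg FFM)."""
    return SubjectRecord("S001", "male", "TT", weight_kg=100.0,
                         height_m=1.80, ffm_kg=58.0, fat_kg=35.0,
                         visceral_fat_g=900.0, android_gynoid_ratio=0.90)


@pytest.fixture(scope="session")
def noise_free_params() -> ClampSimParams:
    return ClampSimParams(cv_glucose=0.0, cv_ttr=0.0, cv_insulin=0.0)


@pytest.fixture(scope="session")
def noise_free_clamp(subject, noise_free_params):
    """One noise-free simulated clamp shared across kinetics tests."""
    return simulate_clamp(subject, noise_free_params, seed=12345)
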