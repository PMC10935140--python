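import math

import pytest
from hypothesis import HealthCheck, settings

from wristfall import pipeline, synthetic_data as sd

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """Reduced 3-source corpus (4 subjects each) for cheap e2e tests."""
    out = tmp_path_factory.mktemp("small_corpus")
    return pipeline.build_corpus(out, config=sd.default_config(
        seed=1, n_subjects=4))


@pytest.fixture(scope="session")
def default_corpus(tmp_path_factory):
    """The full default study corpus (3 sources x 12 subjects), built once
    through the complete generate -> write -> harmonize -> featurize path."""
    out = tmp_path_factory.mktemp("default_corpus")
    return pipeline.build_corpus(out, seed=0)


@pytest.fixture()
def walk_profile():
    return sd.ActivityProfile(activity_id=1, name="walk", is_fall=False,
                              oscillation_freq=1.8, oscillation_amp=0.25)


@pytest.fixture()
def fall_profile():
    return sd.ActivityProfile(
        activity_id=5, name="fall_forward", is_fall=True, impact_peak=3.0,
        impact_duration=0.4, post_impact_orientation_change=math.pi / 2,
        gyro_peak=4.0, noise_std=0.02)
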