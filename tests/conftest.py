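import pytest
from hypothesis import HealthCheck, settings

import gazeclust as gc

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_design():
    return gc.generate_design(6, 6, 3)


@pytest.fixture(scope="session")
def small_params():
    return gc.SyntheticParams(n_subjects=6, n_items=6)


@pytest.fixture(scope="session")
def small_gaze(small_design, small_params):
    return gc.generate_gaze(small_design, small_params, seed=5)


@pytest.fixture(scope="session")
def small_binned(small_gaze):
    return gc.bin_samples(small_gaze, 50.0, (0.0, 2500.0))
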