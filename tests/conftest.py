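import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from gaitcascade.events import EventLabel
from gaitcascade.pipeline import make_split, run_baseline
from gaitcascade.synthetic import GaitSimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_config():
    return GaitSimConfig(seed=123, duration=30.0)


@pytest.fixture(scope="session")
def tiny_recordings(sim_config):
    """A small six-event synthetic dataset (two 30 s recordings per event)."""
    return simulate_dataset(sim_config, {e: 2 for e in EventLabel})


@pytest.fixture(scope="session")
def tiny_split():
    """A small master split (15 s recordings, coarse stride) for quick training."""
    return make_split(seed=3, counts={e: 3 for e in EventLabel}, duration=15.0, stride=4)


@pytest.fixture(scope="session")
def baseline_result():
    """The full-size baseline run shared by the learnability checks."""
    return run_baseline(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
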