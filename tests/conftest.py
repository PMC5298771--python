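import numpy as np
import pytest
from hypothesis import settings

from sisfall.io import AccelTrace
from sisfall.synth import SynthConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def young_trials():
    """Default young-cohort dataset: 200 ADLs + 100 falls at protocol durations."""
    trials, manifest = generate_dataset(200, 100, SynthConfig(seed=42))
    return trials, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_trace(rng, n=400, fs=200.0, scale=1.0):
    """A random, gravity-offset 3-axis trace."""
    a = rng.standard_normal((n, 3)) * scale
    a[:, 1] += 1.0
    return AccelTrace(fs=fs, ax=a[:, 0], ay=a[:, 1], az=a[:, 2])


@pytest.fixture()
def small_synth_config():
    """Short-duration generator config for fast structural tests."""
    return SynthConfig(
        seed=7,
        adl_duration_s={"walk": 8.0, "jog": 8.0, "sit": 8.0, "jump": 8.0},
        fall_duration_s=12.0,
    )
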