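import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmnstudy.paradigm import (ParadigmConfig, generate_paradigm,
                               schedule_events)
from mmnstudy.synthetic_eeg import (ROI_CHANNELS, ZERO_NOISE, ChannelLayout,
                                    sample_cohort, simulate_subject)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Compact montage for unit tests that only need ROI + mastoids + EOG.
SMALL_LAYOUT = ChannelLayout(
    labels=ROI_CHANNELS + ("M1", "M2", "EOG_lower", "EOG_canthus"))


@pytest.fixture(scope="session")
def default_config() -> ParadigmConfig:
    return ParadigmConfig(seed=7)


@pytest.fixture(scope="session")
def small_config() -> ParadigmConfig:
    """Two short blocks; keeps simulation-based tests fast."""
    return ParadigmConfig(n_blocks=2, trials_per_block=21, n_warmup=4, seed=7)


@pytest.fixture(scope="session")
def default_events(default_config):
    return schedule_events(generate_paradigm(default_config), default_config)


@pytest.fixture(scope="session")
def small_events(small_config):
    return schedule_events(generate_paradigm(small_config), small_config)


@pytest.fixture(scope="session")
def meanfixed_profile():
    """A decompensated-group subject pinned exactly at the group means."""
    cohort = sample_cohort(1, seed=3, amplitude_sd_scale=0.0,
                           latency_sd_scale=0.0)
    return next(p for p in cohort if p.group == "decompensated")


@pytest.fixture(scope="session")
def noisefree_recording(meanfixed_profile, small_events):
    return simulate_subject(meanfixed_profile, small_events, noise=ZERO_NOISE)


@pytest.fixture(scope="session")
def roi_times_ms():
    """A 1,024 Hz time axis spanning -50..900 ms, as epoching produces."""
    fs = 1024.0
    n0, n1 = round(-50 / 1000 * fs), round(900 / 1000 * fs)
    return np.arange(n0, n1 + 1) / fs * 1000.0
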