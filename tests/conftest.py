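import dataclasses

import numpy as np
import pytest

from turnkin import GroupProfile, generate_trial
from turnkin.pipeline import PipelineConfig, analyze_trial

FS = 60.0


def quiet_profile(group: str = "SS", **overrides) -> GroupProfile:
    """Default group profile with noise switched off (exact ground truth)."""
    prof = GroupProfile.for_group(group)
    prof.gyro_noise_sd = 0.0
    prof.angle_noise_sd = 0.0
    for key, val in overrides.items():
        setattr(prof, key, val)
    return prof


def fixed(value: float):
    """Degenerate truncated normal that always returns *value*."""
    from turnkin import TruncNormal
    return TruncNormal(value, 0.0, value - 1e-9, value + 1e-9)


@pytest.fixture(scope="session")
def ss_trial():
    """One noisy SS trial at default profile settings."""
    return generate_trial(GroupProfile.for_group("SS"), seed=11)


@pytest.fixture(scope="session")
def quiet_trial():
    """One noise-free SS trial (features should match ground truth)."""
    return generate_trial(quiet_profile("SS"), seed=11)


@pytest.fixture(scope="session")
def analyzed_quiet(quiet_trial):
    """(events, partitions, records) for the noise-free trial."""
    return analyze_trial(quiet_trial, PipelineConfig())


def bell_pulse(t, start, width, amp):
    """Raised-cosine swing pulse on [start, start+width]."""
    g = np.zeros_like(t)
    m = (t >= start) & (t <= start + width)
    g[m] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[m] - start) / width))
    return g
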