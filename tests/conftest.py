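import numpy as np
import pytest

from stsbalance import (
    InertialRecording,
    RecordingMetadata,
    SlbSimConfig,
    StsSimConfig,
    TrialType,
    simulate_slb,
    simulate_sts,
)


@pytest.fixture
def sts_meta():
    return RecordingMetadata(
        user_id="u1", trial_type=TrialType.STS, started_at="2023-01-02T09:00:00",
        sample_rate_hz=100.0, device_label="test",
    )


@pytest.fixture
def small_recording(sts_meta):
    """Tiny valid recording: 10 uniform samples at 100 Hz."""
    n = 10
    rng = np.random.default_rng(0)
    return InertialRecording(
        t=np.arange(n) / 100.0,
        accel=rng.normal(0, 0.01, (n, 3)) + np.array([0.0, 9.81, 0.0]),
        gyro=rng.normal(0, 0.01, (n, 3)),
        mag=rng.normal(0, 0.5, (n, 3)) + np.array([20.0, -5.0, 43.0]),
        meta=sts_meta,
    )


@pytest.fixture
def clean_sts():
    """Noise-free 5-rep sit-to-stand recording with fixed 3.8-s cycles."""
    cfg = StsSimConfig(
        noise_gyro_sd=0.0, noise_accel_sd=0.0, rep_cycle_sd_s=0.0, seed=0
    )
    return simulate_sts(cfg)


@pytest.fixture
def default_slb():
    return simulate_slb(SlbSimConfig(seed=11))
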