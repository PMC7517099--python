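import numpy as np
import pytest

from memmhar import (ActivityProfile, InertialRecording, generate_dataset,
                     sports6_profiles)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording():
    """1000-sample 6-channel recording at 100 Hz with one label."""
    t = np.arange(1000) / 100.0
    samples = np.column_stack(
        [np.sin(2 * np.pi * (1 + c) * t) for c in range(6)]
    )
    return InertialRecording(
        subject_id="s1",
        sampling_rate_hz=100.0,
        channels=["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"],
        samples=samples,
        labels="walking",
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 subjects x 6 sport-like activities, 12 s each at 100 Hz."""
    return generate_dataset(sports6_profiles(), n_subjects=3,
                            duration_s=12.0, fs=100.0, seed=1)


@pytest.fixture
def quiet_profile():
    """Noise- and outlier-free single-frequency profile."""
    return ActivityProfile(
        name="quiet", base_freq_hz=2.5, amplitude=1.0,
        phase_jitter=0.0, noise_sd=0.0, outlier_rate=0.0,
    )
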