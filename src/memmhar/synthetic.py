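"""Synthetic multi-subject inertial datasets.

Each activity is modelled as a per-channel harmonic signature — DC offset
plus a sinusoid at an activity-specific frequency and amplitude — with
additive Gaussian sensor noise and occasional impulsive outliers
(Bernoulli per sample).  Subjects differ by a deterministic ±10%
amplitude scaling and by their noise realizations.  This is deliberately
not a biomechanical gait model: it is the simplest stated world that
exercises every pipeline stage (impulses for the filters, distinct
frequencies/amplitudes for the spectral and statistical features,
waveform shape for the LBP block).

Two presets ship: ``sports6`` (six sport-like activities, echoing a
6-class three-sensor dataset) and ``daily12`` (twelve daily-living
activities, echoing a 12-class dataset).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import DEFAULT_CHANNELS, InertialRecording

_N_CHANNELS = len(DEFAULT_CHANNELS)


def _crc(text: str) -> int:
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@dataclass
class ActivityProfile:
    """Harmonic signature of one activity class.

    ``base_freq_hz``, ``amplitude`` and ``dc_offset`` are per-channel
    arrays (one entry per accelerometer/gyroscope channel);
    ``phase_jitter`` is the standard deviation, in radians, of the
    per-recording phase draw.  ``outlier_rate`` is the per-sample
    Bernoulli probability of an impulsive spike of magnitude
    ``outlier_scale`` times the channel amplitude.
    """

    name: str
    base_freq_hz: np.ndarray
    amplitude: np.ndarray
    dc_offset: np.ndarray = None
    phase_jitter: float = 0.3
    noise_sd: float = 0.2
    outlier_rate: float = 0.005
    outlier_scale: float = 8.0

    def __post_init__(self) -> None:
        self.base_freq_hz = np.broadcast_to(
            np.asarray(self.base_freq_hz, dtype=float), (_N_CHANNELS,)
        ).copy()
        self.amplitude = np.broadcast_to(
            np.asarray(self.amplitude, dtype=float), (_N_CHANNELS,)
        ).copy()
        if self.dc_offset is None:
            self.dc_offset = np.zeros(_N_CHANNELS)
        self.dc_offset = np.broadcast_to(
            np.asarray(self.dc_offset, dtype=float), (_N_CHANNELS,)
        ).copy()
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def subject_amplitude_scale(subject_id: str, seed: int,
                            n_channels: int = _N_CHANNELS) -> np.ndarray:
    """Deterministic per-subject, per-channel amplitude factors in
    [0.9, 1.1] — the inter-subject variability of the stated world."""
    rng = np.random.default_rng([seed, _crc(subject_id)])
    return 1.0 + 0.1 * rng.uniform(-1.0, 1.0, size=n_channels)


def _generate(profile: ActivityProfile, subject_id: str, duration_s: float,
              fs: float, seed: int):
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError("duration_s * fs must be at least 1 sample")
    if np.any(profile.base_freq_hz >= fs / 2):
        raise ValueError(
            f"profile {profile.name!r} has frequencies at or above Nyquist "
            f"({fs / 2} Hz)"
        )
    scale = subject_amplitude_scale(subject_id, seed)
    rng = np.random.default_rng([seed, _crc(subject_id), _crc(profile.name)])
    t = np.arange(n) / fs
    samples = np.empty((n, _N_CHANNELS))
    masks = np.zeros((n, _N_CHANNELS), dtype=bool)
    for c in range(_N_CHANNELS):
        amp = profile.amplitude[c] * scale[c]
        phase = rng.normal(0.0, profile.phase_jitter) if profile.phase_jitter > 0 else 0.0
        x = profile.dc_offset[c] + amp * np.sin(
            2 * np.pi * profile.base_freq_hz[c] * t + phase
        )
        if profile.noise_sd > 0:
            x = x + rng.normal(0.0, profile.noise_sd, size=n)
        if profile.outlier_rate > 0:
            mask = rng.random(n) < profile.outlier_rate
            signs = rng.choice([-1.0, 1.0], size=n)
            x = x + mask * signs * profile.outlier_scale * profile.amplitude[c]
            masks[:, c] = mask
        samples[:, c] = x
    recording = InertialRecording(
        subject_id=subject_id,
        sampling_rate_hz=float(fs),
        channels=list(DEFAULT_CHANNELS),
        samples=samples,
        labels=profile.name,
    )
    return recording, masks


def generate_recording(profile: ActivityProfile, subject_id: str,
                       duration_s: float, fs: float, seed: int) -> InertialRecording:
    """One labelled recording of ``profile`` for one subject.

    Deterministic per (profile, subject_id, seed): the same arguments
    always produce the identical recording.
    """
    return _generate(profile, subject_id, duration_s, fs, seed)[0]


def generate_dataset(profiles, n_subjects: int, duration_s: float = 60.0,
                     fs: float = 100.0, seed: int = 42) -> list[InertialRecording]:
    """Class-balanced dataset: one recording per (subject, activity)."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 activity profiles")
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    recordings = []
    for i in range(n_subjects):
        subject = f"subj{i:02d}"
        for profile in profiles:
            recordings.append(
                generate_recording(profile, subject, duration_s, fs, seed)
            )
    return recordings


# ---------------------------------------------------------------------------
# presets

# Channel layout: acc_x, acc_y, acc_z, gyr_x, gyr_y, gyr_z.  Frequencies
# are cadence-like fundamentals (Hz); accelerometer amplitudes roughly in
# m/s^2, gyroscope in rad/s; acc_z carries a gravity-like offset.

_GRAVITY_OFFSET = np.array([0.0, 0.0, 9.8, 0.0, 0.0, 0.0])


def sports6_profiles() -> list[ActivityProfile]:
    """Six sport-like activity signatures."""
    spec = [
        # name, base freq, acc amp, gyr amp
        ("football", 2.6, 3.0, 1.6),
        ("skipping", 3.4, 4.0, 1.0),
        ("basketball", 2.0, 2.4, 1.3),
        ("badminton", 1.4, 1.6, 2.2),
        ("cycling", 1.0, 0.9, 0.7),
        ("table_tennis", 1.8, 0.8, 1.8),
    ]
    profiles = []
    for name, f0, acc_amp, gyr_amp in spec:
        freq = f0 * np.array([1.0, 1.25, 0.75, 1.5, 0.9, 1.1])
        amp = np.array([acc_amp, 0.8 * acc_amp, 0.6 * acc_amp,
                        gyr_amp, 0.8 * gyr_amp, 1.2 * gyr_amp])
        profiles.append(
            ActivityProfile(name=name, base_freq_hz=freq, amplitude=amp,
                            dc_offset=_GRAVITY_OFFSET)
        )
    return profiles


def daily12_profiles() -> list[ActivityProfile]:
    """Twelve daily-living activity signatures, including near-static ones."""
    spec = [
        ("jumping_up", 3.0, 4.5, 1.2),
        ("running_forward", 2.9, 3.6, 1.5),
        ("walking_forward", 1.9, 1.8, 0.9),
        ("elevator_down", 0.25, 0.25, 0.05),
        ("elevator_up", 0.35, 0.25, 0.05),
        ("sitting", 0.2, 0.08, 0.03),
        ("standing", 0.3, 0.06, 0.02),
        ("sleeping", 0.15, 0.04, 0.01),
        ("walking_left", 1.7, 1.6, 1.4),
        ("walking_right", 1.75, 1.6, 1.1),
        ("walking_downstairs", 1.5, 2.2, 1.0),
        ("walking_upstairs", 1.3, 2.0, 1.1),
    ]
    profiles = []
    for name, f0, acc_amp, gyr_amp in spec:
        freq = f0 * np.array([1.0, 1.2, 0.8, 1.4, 1.0, 0.9])
        amp = np.array([acc_amp, 0.7 * acc_amp, 0.9 * acc_amp,
                        gyr_amp, 1.1 * gyr_amp, 0.8 * gyr_amp])
        profiles.append(
            ActivityProfile(name=name, base_freq_hz=freq, amplitude=amp,
                            dc_offset=_GRAVITY_OFFSET, noise_sd=0.15)
        )
    return profiles


PRESETS = {"sports6": sports6_profiles, "daily12": daily12_profiles}


def preset_profiles(name: str) -> list[ActivityProfile]:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
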