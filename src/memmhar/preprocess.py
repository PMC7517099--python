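"""Denoising filters and fixed-sliding-window segmentation.

Three denoising options are provided, matching how inertial HAR pipelines
clean raw accelerometer/gyroscope streams before feature extraction:

* median filter — removes impulsive noise (the package default),
* Savitzky–Golay — local least-squares polynomial smoothing,
* Hampel — outlier detection/replacement via the scaled median absolute
  deviation (MAD).

All filters preserve signal length.  Segmentation cuts a recording into
fixed-length windows with fractional overlap; each window carries the
majority per-sample label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import median_filter as _nd_median
from scipy.signal import savgol_filter as _savgol

from .errors import EmptyInputError
from .io import InertialRecording

#: Consistency factor making the MAD an unbiased sigma estimate under
#: Gaussian noise.
MAD_SCALE = 1.4826


@dataclass
class WindowedSegment:
    """A fixed-length multi-channel slice of a recording.

    ``start_index`` is the 0-based sample index of the window's first row
    in the source recording; ``label`` is the within-window majority label.
    """

    samples: np.ndarray  # (window_length, n_channels)
    label: str
    subject_id: str
    start_index: int


def median_filter(signal, kernel: int):
    """Sliding-median filter with replicate edge padding.

    ``kernel`` must be odd and no longer than the signal.  Removes
    impulsive spikes while leaving monotone trends nearly untouched.
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    if kernel <= 0 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and positive, got {kernel}")
    if kernel > n:
        raise ValueError(f"kernel {kernel} exceeds signal length {n}")
    size = (1,) * (x.ndim - 1) + (kernel,)
    return _nd_median(x, size=size, mode="nearest")


def savitzky_golay(signal, window: int, polyorder: int):
    """Savitzky–Golay smoothing: local least-squares polynomial fit.

    Signals that are exact polynomials of degree <= ``polyorder`` are
    reproduced unchanged (edge windows are fitted with a single
    polynomial, preserving that identity at the boundaries).
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    if window <= 0 or window % 2 == 0:
        raise ValueError(f"window must be odd and positive, got {window}")
    if polyorder < 0 or polyorder >= window:
        raise ValueError(
            f"polyorder {polyorder} must satisfy 0 <= polyorder < window {window}"
        )
    if window > n:
        raise ValueError(f"window {window} exceeds signal length {n}")
    return _savgol(x, window_length=window, polyorder=polyorder,
                   axis=-1, mode="interp")


def hampel_filter(signal, half_window: int = 3, n_sigmas: float = 3.0):
    """Hampel outlier filter.

    Sample i is flagged and replaced by the local median iff
    ``|x_i - med_i| > n_sigmas * 1.4826 * MAD_i`` over the window of
    ``2 * half_window + 1`` samples centred at i.  The first and last
    ``half_window`` samples have no full window and are never flagged.

    Returns ``(filtered, outlier_mask)``; a constant signal yields zero
    flags (deviation 0 is not > 0).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("hampel_filter expects a 1-D signal")
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    if n_sigmas <= 0:
        raise ValueError("n_sigmas must be positive")
    width = 2 * half_window + 1
    n = x.size
    if width > n:
        raise ValueError(f"window {width} exceeds signal length {n}")
    windows = sliding_window_view(x, width)          # (n - width + 1, width)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    center = x[half_window : n - half_window]
    flagged = np.abs(center - med) > n_sigmas * MAD_SCALE * mad
    mask = np.zeros(n, dtype=bool)
    mask[half_window : n - half_window] = flagged
    filtered = x.copy()
    filtered[mask] = med[flagged]
    return filtered, mask


def zscore_channels(samples):
    """Per-channel z-scoring (optional normalization stage).

    Channels with zero spread are centred but left unscaled.
    """
    x = np.asarray(samples, dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return (x - mean) / std


def apply_filter(samples, kind: str = "median", **params):
    """Apply a named denoising filter to every channel of a sample matrix.

    ``kind`` is one of ``{"median", "savgol", "hampel", "none"}``;
    ``params`` are forwarded to the underlying filter.
    """
    x = np.asarray(samples, dtype=float)
    if kind == "none":
        return x
    if kind == "median":
        return median_filter(x.T, kernel=params.get("kernel", 5)).T
    if kind == "savgol":
        return savitzky_golay(
            x.T, window=params.get("window", 11), polyorder=params.get("polyorder", 3)
        ).T
    if kind == "hampel":
        out = np.empty_like(x)
        for c in range(x.shape[1]):
            out[:, c], _ = hampel_filter(
                x[:, c],
                half_window=params.get("half_window", 3),
                n_sigmas=params.get("n_sigmas", 3.0),
            )
        return out
    raise ValueError(f"unknown filter kind {kind!r}")


def _majority_label(labels) -> str:
    """Most frequent label; ties go to the label appearing earliest."""
    values, first_idx, counts = np.unique(
        np.asarray(labels, dtype=str), return_index=True, return_counts=True
    )
    best = counts.max()
    tied = counts == best
    return str(values[tied][np.argmin(first_idx[tied])])


def segment_windows(
    recording: InertialRecording,
    window_seconds: float = 4.0,
    overlap_fraction: float = 0.5,
) -> list[WindowedSegment]:
    """Cut a recording into fixed sliding windows.

    The window length is ``round(window_seconds * sampling_rate)`` samples
    and the hop ``round(window_length * (1 - overlap_fraction))`` (at least
    one sample).  Trailing samples that do not fill a window are dropped.
    """
    if recording.n_samples == 0:
        raise EmptyInputError("cannot segment an empty recording")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    window_length = int(round(window_seconds * recording.sampling_rate_hz))
    if window_length < 1:
        raise ValueError("window shorter than one sample")
    hop = max(1, int(round(window_length * (1.0 - overlap_fraction))))
    segments = []
    for start in range(0, recording.n_samples - window_length + 1, hop):
        stop = start + window_length
        segments.append(
            WindowedSegment(
                samples=recording.samples[start:stop],
                label=_majority_label(recording.labels[start:stop]),
                subject_id=recording.subject_id,
                start_index=start,
            )
        )
    return segments
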