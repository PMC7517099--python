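"""Multifused feature extraction for windowed inertial signals.

Each window contributes, per channel and in channel order:

==================  ======  =============================================
block               length  content
==================  ======  =============================================
``stat``            4       mean, variance (n-1 denominator), min, max
``lbp``             2**P    normalized histogram of 1-D local binary
                            pattern codes with P neighbours
``wht``             m       first m Walsh–Hadamard coefficients / N
``czt``             b       magnitudes of b chirp-z coefficients on the
                            unit circle over [0, Nyquist)
``hilbert``         3       envelope mean, envelope variance, mean |imag|
                            of the analytic signal (10% edge margins
                            trimmed to suppress transform edge effects)
``deriv``           3       mean, variance, max-abs of the first-order
                            difference
==================  ======  =============================================

With the defaults (P=4, m=8, b=8) a 6-channel window yields a 252-slot
vector.  The layout is identical for every window of a run, which the
codebook and the sequence classifier both require.

All transform primitives accept N-D input and operate along the last
axis, so the extractor can process a whole batch of windows per channel
in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import czt as _scipy_czt
from scipy.signal import hilbert as _scipy_hilbert
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptyInputError
from .preprocess import WindowedSegment


# ---------------------------------------------------------------------------
# statistical features


@dataclass
class StatisticalSummary:
    """Mean, variance (n-1 denominator) and extrema of one signal."""

    mean: float
    variance: float
    min: float
    max: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.variance, self.min, self.max])


def statistical_features(signal) -> StatisticalSummary:
    """Per-window statistical summary: mean, sample variance, min, max."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("statistical_features needs a 1-D signal of length >= 2")
    return StatisticalSummary(
        mean=float(x.mean()),
        variance=float(x.var(ddof=1)),
        min=float(x.min()),
        max=float(x.max()),
    )


def _stat_block(batch: np.ndarray) -> np.ndarray:
    """(n, L) batch -> (n, 4) [mean, var(ddof=1), min, max]."""
    return np.column_stack(
        [batch.mean(axis=1), batch.var(axis=1, ddof=1),
         batch.min(axis=1), batch.max(axis=1)]
    )


# ---------------------------------------------------------------------------
# chirp z-transform


@dataclass
class CZTParams:
    """Contour parameters for the chirp z-transform.

    The transform evaluates ``X_k = sum_n x(n) * z_k**(-n)`` on the spiral
    ``z_k = A * W**(-k)`` for ``k = 0 .. B-1``.  The defaults, set via
    :meth:`unit_circle`, place the points uniformly on the unit circle.
    """

    num_points: int
    start_point: complex = 1 + 0j  # A
    ratio: complex = field(default=None)  # W

    def __post_init__(self) -> None:
        if self.num_points < 1:
            raise ValueError("num_points must be >= 1")
        if self.ratio is None:
            self.ratio = np.exp(-2j * np.pi / self.num_points)
        if abs(self.start_point) == 0 or abs(self.ratio) == 0:
            raise ValueError("A and W must be nonzero")

    @classmethod
    def unit_circle(cls, num_points: int) -> "CZTParams":
        """DFT-equivalent contour: A=1, W=exp(-2*pi*i/B)."""
        return cls(num_points=num_points)

    @classmethod
    def half_circle(cls, num_points: int) -> "CZTParams":
        """B points covering [0, Nyquist): A=1, W=exp(-pi*i/B)."""
        return cls(num_points=num_points, ratio=np.exp(-1j * np.pi / num_points))


def chirp_z_transform(signal, params: CZTParams):
    """Chirp z-transform along the contour ``z_k = A * W**(-k)``.

    Computed with Bluestein's fast-convolution algorithm
    (scipy.signal.czt).  With ``A = 1`` and ``W = exp(-2*pi*i/N)`` this is
    exactly the N-point DFT.
    """
    x = np.asarray(signal, dtype=float)
    if x.shape[-1] == 0:
        raise EmptyInputError("chirp_z_transform: empty signal")
    return _scipy_czt(
        x, m=params.num_points, w=params.ratio, a=params.start_point, axis=-1
    )


def czt_features(signal, num_bins: int):
    """Magnitudes of ``num_bins`` chirp-z coefficients over [0, Nyquist).

    Bin k sits at normalized angular frequency ``pi * k / num_bins``,
    i.e. physical frequency ``k * fs / (2 * num_bins)``.
    """
    x = np.asarray(signal, dtype=float)
    if num_bins < 1:
        raise ValueError("num_bins must be >= 1")
    if num_bins > x.shape[-1]:
        raise ValueError(
            f"num_bins {num_bins} exceeds signal length {x.shape[-1]}"
        )
    return np.abs(chirp_z_transform(x, CZTParams.half_circle(num_bins)))


# ---------------------------------------------------------------------------
# analytic signal (Hilbert)

#: Fraction of the window discarded at each end before summarizing the
#: analytic signal; the FFT construction rings near the boundaries.
_HILBERT_EDGE_FRACTION = 0.1


def hilbert_analytic(signal):
    """Analytic signal via the FFT: negative frequencies zeroed, positive
    doubled (DC/Nyquist untouched).  The real part reproduces the input."""
    x = np.asarray(signal, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("hilbert_analytic needs at least 2 samples")
    return _scipy_hilbert(x, axis=-1)


def hilbert_features(signal):
    """Three-slot summary of the analytic signal.

    Returns ``[envelope mean, envelope variance, mean |imaginary part|]``
    computed with 10% edge margins trimmed at each end.
    """
    analytic = hilbert_analytic(signal)
    n = analytic.shape[-1]
    trim = max(1, int(round(_HILBERT_EDGE_FRACTION * n)))
    core = analytic[..., trim : n - trim]
    env = np.abs(core)
    out = np.stack(
        [env.mean(axis=-1), env.var(axis=-1), np.abs(core.imag).mean(axis=-1)],
        axis=-1,
    )
    return out


# ---------------------------------------------------------------------------
# 1-D local binary patterns


def _lbp_codes_batch(batch: np.ndarray, num_neighbors: int) -> np.ndarray:
    half = num_neighbors // 2
    windows = sliding_window_view(batch, num_neighbors + 1, axis=-1)
    center = windows[..., half]
    neighbors = np.concatenate(
        [windows[..., :half], windows[..., half + 1 :]], axis=-1
    )
    bits = neighbors >= center[..., None]  # ties take the 1-branch
    powers = 1 << np.arange(num_neighbors)  # leftmost neighbour = LSB
    return (bits * powers).sum(axis=-1).astype(np.int64)


def lbp_1d(signal, num_neighbors: int = 4):
    """1-D local binary pattern codes.

    At each position with a full neighbourhood (P/2 samples each side)
    the centre sample is the threshold; neighbour j contributes bit 1 iff
    its value >= threshold.  Bits are read left to right with the oldest
    (leftmost) neighbour as the least significant bit, so each code lies
    in ``[0, 2**P - 1]``.
    """
    x = np.asarray(signal, dtype=float)
    if num_neighbors <= 0 or num_neighbors % 2 != 0:
        raise ValueError("num_neighbors must be even and positive")
    if x.shape[-1] < num_neighbors + 1:
        raise ValueError(
            f"signal length {x.shape[-1]} < num_neighbors + 1 = {num_neighbors + 1}"
        )
    return _lbp_codes_batch(x, num_neighbors)


def lbp_histogram(codes, num_neighbors: int):
    """Normalized histogram of LBP codes over all ``2**P`` bins."""
    codes = np.asarray(codes)
    if codes.size == 0:
        raise EmptyInputError("lbp_histogram: empty code sequence")
    n_bins = 1 << num_neighbors
    if codes.min() < 0 or codes.max() >= n_bins:
        raise ValueError(f"codes out of range [0, {n_bins - 1}]")
    if codes.ndim == 1:
        return np.bincount(codes, minlength=n_bins) / codes.size
    flat = codes + (np.arange(codes.shape[0]) * n_bins)[:, None]
    hist = np.bincount(flat.ravel(), minlength=codes.shape[0] * n_bins)
    return hist.reshape(codes.shape[0], n_bins) / codes.shape[1]


# ---------------------------------------------------------------------------
# Walsh–Hadamard transform


def walsh_hadamard(signal):
    """Unnormalized Walsh–Hadamard transform in natural (Hadamard) order.

    The input is zero-padded to the next power of two N; applying the
    transform twice returns N times the padded input.  Implemented as the
    standard in-place butterfly (O(N log N)).
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    if n == 0:
        raise EmptyInputError("walsh_hadamard: empty signal")
    size = 1 << max(0, (n - 1).bit_length())
    if size != n:
        pad = [(0, 0)] * (x.ndim - 1) + [(0, size - n)]
        x = np.pad(x, pad)
    y = x.copy()
    h = 1
    while h < size:
        shaped = y.reshape(*y.shape[:-1], size // (2 * h), 2, h)
        a = shaped[..., 0, :]
        b = shaped[..., 1, :]
        y = np.stack([a + b, a - b], axis=-2).reshape(*y.shape[:-1], size)
        h *= 2
    return y


def wht_features(signal, num_coeffs: int = 8):
    """First ``num_coeffs`` Walsh–Hadamard coefficients divided by N,
    making the block energy-comparable across window sizes."""
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    size = 1 << max(0, (n - 1).bit_length()) if n else 0
    if num_coeffs < 1 or num_coeffs > size:
        raise ValueError(
            f"num_coeffs {num_coeffs} not in [1, padded length {size}]"
        )
    return walsh_hadamard(x)[..., :num_coeffs] / size


# ---------------------------------------------------------------------------
# first-order derivatives


def first_order_derivative(window, spacing: float = 1.0):
    """Per-channel forward-difference summary.

    Computes ``(x[i+1] - x[i]) / spacing`` per channel and summarizes each
    channel by (mean, variance, max absolute), concatenated in channel
    order: 3 slots per channel.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    if w.shape[0] < 2:
        raise ValueError("first_order_derivative needs at least 2 rows")
    d = np.diff(w, axis=0) / spacing
    summary = np.stack(
        [d.mean(axis=0), d.var(axis=0), np.abs(d).max(axis=0)], axis=-1
    )
    return summary.ravel()


def _deriv_block(batch: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """(n, L) batch -> (n, 3) derivative summaries."""
    d = np.diff(batch, axis=-1) / spacing
    return np.column_stack(
        [d.mean(axis=-1), d.var(axis=-1), np.abs(d).max(axis=-1)]
    )


# ---------------------------------------------------------------------------
# the multifused extractor


@dataclass
class FeatureConfig:
    """Sizes of the tunable feature blocks."""

    lbp_neighbors: int = 4
    wht_coeffs: int = 8
    czt_bins: int = 8


@dataclass
class FeatureVector:
    """A fixed-length feature vector plus its named slot layout."""

    values: np.ndarray
    layout: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        total = sum(length for _, _, length in self.layout)
        if total != self.values.size:
            raise ValueError(
                f"layout covers {total} slots but vector has {self.values.size}"
            )


_BLOCK_NAMES = ("stat", "lbp", "wht", "czt", "hilbert", "deriv")


def feature_layout(channels, config: FeatureConfig) -> list[tuple[str, str, int]]:
    """Per-channel block layout of the multifused vector."""
    lengths = {
        "stat": 4,
        "lbp": 1 << config.lbp_neighbors,
        "wht": config.wht_coeffs,
        "czt": config.czt_bins,
        "hilbert": 3,
        "deriv": 3,
    }
    return [
        (name, str(chan), lengths[name])
        for chan in channels
        for name in _BLOCK_NAMES
    ]


def _extract_batch(windows: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """(n_windows, L, C) -> (n_windows, C * block_total) feature matrix."""
    n, length, n_channels = windows.shape
    blocks = []
    for c in range(n_channels):
        s = np.ascontiguousarray(windows[:, :, c])
        codes = _lbp_codes_batch(s, config.lbp_neighbors)
        blocks.extend(
            [
                _stat_block(s),
                lbp_histogram(codes, config.lbp_neighbors),
                wht_features(s, config.wht_coeffs),
                czt_features(s, config.czt_bins),
                hilbert_features(s),
                _deriv_block(s),
            ]
        )
    return np.concatenate(blocks, axis=1)


def extract_multifused(window: WindowedSegment, config: FeatureConfig | None = None) -> FeatureVector:
    """Extract the multifused feature vector of one window.

    Concatenates, per channel in channel order: statistical summary (4),
    LBP histogram (2**P), Walsh–Hadamard block, chirp-z block, analytic-
    signal summary (3) and derivative summary (3).  Deterministic for a
    fixed window and configuration.
    """
    config = config or FeatureConfig()
    samples = np.asarray(window.samples, dtype=float)
    values = _extract_batch(samples[None, :, :], config)[0]
    channels = [f"ch{c}" for c in range(samples.shape[1])]
    return FeatureVector(values=values, layout=feature_layout(channels, config))


class MultifusedFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer turning windowed segments into multifused feature rows.

    Parameters
    ----------
    lbp_neighbors : int, default 4
        Even neighbourhood size P of the 1-D LBP; the histogram block has
        ``2**P`` bins.
    wht_coeffs : int, default 8
        Number of leading Walsh–Hadamard coefficients kept per channel.
    czt_bins : int, default 8
        Number of chirp-z magnitude bins over [0, Nyquist) per channel.
    channel_names : sequence of str, optional
        Names used in the recorded layout; inferred as ``ch0..`` if absent.

    Attributes
    ----------
    layout_ : list of (feature, channel, length)
        Slot layout of the transformed matrix.
    n_features_out_ : int
        Number of feature columns.
    """

    def __init__(self, lbp_neighbors: int = 4, wht_coeffs: int = 8,
                 czt_bins: int = 8, channel_names=None):
        self.lbp_neighbors = lbp_neighbors
        self.wht_coeffs = wht_coeffs
        self.czt_bins = czt_bins
        self.channel_names = channel_names

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            lbp_neighbors=self.lbp_neighbors,
            wht_coeffs=self.wht_coeffs,
            czt_bins=self.czt_bins,
        )

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, np.ndarray):
            arr = X
        else:
            arr = np.stack([np.asarray(w.samples, dtype=float) for w in X])
        if arr.ndim != 3:
            raise ValueError("expected (n_windows, window_length, n_channels)")
        return arr

    def fit(self, X, y=None):
        arr = self._as_array(X)
        n_channels = arr.shape[2]
        names = (
            list(self.channel_names)
            if self.channel_names is not None
            else [f"ch{c}" for c in range(n_channels)]
        )
        if len(names) != n_channels:
            raise ValueError("channel_names length does not match data")
        self.layout_ = feature_layout(names, self._config())
        self.n_features_out_ = sum(length for _, _, length in self.layout_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "layout_"):
            raise RuntimeError("MultifusedFeatureExtractor is not fitted")
        arr = self._as_array(X)
        out = _extract_batch(arr, self._config())
        if out.shape[1] != self.n_features_out_:
            raise ValueError("channel count changed between fit and transform")
        return out
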