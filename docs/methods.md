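# Methods

This note records the model, the numerical choices and the defaults the
package ships with, and what the synthetic stated world does and does
not establish.

## Pipeline

1. **Denoising.**  Default: sliding median filter, kernel 5, replicate
   edge padding — it removes the impulsive spikes that dominate IMU
   noise while preserving edges.  Alternatives selectable per config:
   Savitzky–Golay (window 11, polyorder 3) and Hampel (half-window 3,
   3 sigmas).  The Hampel threshold uses the 1.4826·MAD scaling so
   "sigmas" are Gaussian-consistent; the first/last half-window samples
   have no complete neighbourhood and are never flagged.
   Savitzky–Golay uses polynomial edge fitting (`mode="interp"`) rather
   than replicate padding: replicate padding silently breaks the
   filter's defining property of reproducing low-order polynomials at
   the boundaries.
2. **Windowing.**  Fixed sliding windows, default 4.0 s with 50%
   overlap (400 samples at 100 Hz, hop 200).  Sub-second frames cannot
   support the Walsh–Hadamard/chirp-z blocks, and multi-second windows
   are the common convention for cyclic daily activities.  A window's
   label is the within-window majority; ties go to the label appearing
   earliest in the window.  Trailing samples that do not fill a window
   are dropped.  Optional per-channel z-scoring of the raw signal is
   off by default.
3. **Features** (per channel, defaults in parentheses):
   * statistical: mean, variance (n−1 denominator), min, max;
   * 1-D LBP (P = 4 neighbours): centre sample is the threshold, ties
     take the 1-branch, leftmost neighbour is the least significant
     bit; the window contributes a 2^P-bin normalized code histogram.
     P = 4 keeps vectors compact; P = 8 is available;
   * Walsh–Hadamard (8 coefficients): natural-order fast transform on
     the zero-padded next power of two, divided by N so windows of
     different length are energy-comparable;
   * chirp-z (8 bins): magnitudes on the unit circle over [0, Nyquist),
     i.e. a zoom-DFT with A = 1, W = exp(−iπ/B), computed by
     Bluestein's algorithm;
   * analytic signal: envelope mean, envelope variance and mean
     absolute quadrature component, with 10% edge margins trimmed
     because the FFT construction rings at window boundaries;
   * first-order derivative: mean, variance, max-absolute of forward
     differences (unit sample spacing; with a fixed sampling rate this
     differs from physical units only by a constant factor).
   Hilbert and derivative sequences are reduced to fixed-length
   summaries because the codebook and the MEMM require equal-length
   vectors per window.
4. **Standardization and codebook.**  Features are z-scored with
   statistics fitted on the training folds only, then (in symbol mode)
   quantized by a K = 64 k-means codebook also fitted on training folds
   only — both to keep held-out subjects out of every fitted statistic.
   K = 64 makes the symbol space an order of magnitude larger than the
   class count while remaining estimable from desk-scale data.  The
   k-means is deterministic: seeded random first centre, farthest-point
   completion, Lloyd iterations (≤ 300, shift tolerance 1e-6), with a
   monotone-distortion assertion; emptied clusters are re-seeded on the
   worst-fit point.
5. **Classifier.**  MEMM with one weight block per previous state
   (including a dedicated start state, since the base case of the
   forward recursion is otherwise undefined), per-target-state weights
   over symbol indicators (symbol mode) or standardized feature values
   (dense mode) plus a bias.  All probabilities are computed in
   log space with max-subtraction; Viterbi ties break toward the lower
   state index.
6. **Evaluation.**  Leave-one-**subject**-out: window-wise leave-one-out
   would place near-duplicate windows of the same subject on both sides
   of a fold and leak subject identity.  Reported numbers are the
   pooled row-normalized confusion matrix, the unweighted mean of
   per-class recalls ("mean accuracy"), and per-class
   precision/recall/F.  Rows or denominators with no support yield 0
   with a degenerate flag rather than NaN.

## Training

The objective is the mean conditional log-likelihood over training
transitions minus `l2·‖w‖²` (default l2 = 1e-3; unpenalized maxent
diverges on separable data).  The gradient per weight slot is the
difference between empirical and model-expected feature counts minus
the penalty term, so an unregularized optimum satisfies the maxent
constraint (verified in the tests to < 1e-3).

Optimizers are full-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) and
AdaDelta (ρ = 0.95, ε = 1e-6), both implemented functionally and
deterministic.  The pipeline trains with Adam at lr = 5e-5 by default;
because that rate is small and the batch is the whole dataset, the
default epoch budget is 2000, chosen from objective-plateau diagnostics
on synthetic runs.  The standalone `Adam` class defaults to the
conventional lr = 1e-3, which is the right general-purpose setting for
callers using it outside the MEMM trainer.  An optional `lr_backoff`
mode retries a halved step whenever the objective decreases; it is off
by default because full-batch steps at the default rate are already
monotone in practice.

Classification accuracy depends on the *ordering* of transition scores,
not their magnitude, so decode quality saturates well before the
constraint residual does; the default budget targets the former.

## Synthetic stated world

Each activity is a per-channel harmonic signature — DC offset (with a
gravity-like 9.8 on acc_z) plus a sinusoid at an activity-specific
frequency (0.15–3.4 Hz fundamentals across the presets, scaled
per channel) and amplitude — with Gaussian sensor noise (sd 0.15–0.2),
phase jitter (sd 0.3 rad) per recording, impulsive outliers (Bernoulli
0.005 per sample, 8× amplitude) and a deterministic ±10% per-subject
amplitude scaling.  Presets: `sports6` (six sport-like classes) and
`daily12` (twelve daily-living classes including near-static ones).
Everything is reproducible from a single seed; per-stage seeds derive
from it via `SeedSequence([seed, crc32(stage)])`.

This world exercises every pipeline stage (impulses for the filters,
distinct spectra for CZT/WHT/Hilbert, waveform shape for LBP,
inter-subject variation for LOOCV), but it is *not* biomechanics: real
signals are non-stationary, multi-harmonic, and differ across subjects
in waveform shape rather than only in amplitude.  A green end-to-end
test therefore establishes that the implementation separates classes
whose signatures differ — not that it would reach any particular
accuracy on real recordings, where similar-motion pairs genuinely
overlap.

## Numerical choices and degenerate inputs

* CSV numerics are written with 17 significant digits and parsed with
  correctly-rounded converters, so file round-trips are bit-exact.
* Constant signals: the Hampel filter defines deviation 0 as not an
  outlier (MAD = 0 flags nothing); the all-ties LBP code is 2^P − 1.
* A codebook refuses to fit with fewer distinct vectors than clusters;
  nearest-centroid ties resolve to the lowest index.
* The MEMM requires ≥ 2 states; a single-state corpus is rejected at
  training time.
* Empty signals, empty datasets and header-only files raise
  `EmptyInputError`; schema violations name the missing column; parse
  failures name the row.

## Known limitations

* No resampling: recordings are assumed to share one sampling rate.
* The MEMM is locally normalized and therefore subject to label bias;
  a globally normalized (CRF-style) variant is out of scope.
* Magnetometer channels, streaming/real-time inference and on-device
  deployment are not modelled.
* Random-forest / neural-network baselines are not reimplemented; any
  scikit-learn classifier can be compared externally on the exported
  feature CSVs.
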