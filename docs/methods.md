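# Methods

`loadtrf` implements a forward ("encoding") analysis of continuous EEG
recorded while people listen to narrated educational multimedia under
two cognitive-load conditions (P = designed to multimedia-learning
principles, low load; NP = violating them, high load). This note
documents the model, the analysis choices, and what the synthetic data
do and do not establish.

## The forward model

The neural response at channel *c* is modeled as a lagged linear
functional of a univariate stimulus feature *S*:

    R_c(t) = Σ_τ TRF_c(τ) · S(t − τ) + ε_c(t),   τ ∈ [−200, 1000] ms

The lag-indexed weights TRF_c(τ) are the temporal response function: the
EEG-level analogue of an impulse response, read like an ERP (early
deflections ≈ sensory components, late ones ≈ semantic processing).
The acausal margin (−200 ms) lets the estimate express anticipatory or
smearing structure without biasing the causal part; the 1-s upper bound
reflects that the auditory/linguistic processing of interest completes
within a second.

With S expanded into a time × lags design matrix (plus an intercept
column), the ridge estimate per channel is

    TRF = (SᵀS + λM)⁻¹ SᵀR

where M is the identity with a zero in the intercept position: the bias
is never penalized, so the λ → ∞ limit is the intercept-only (mean)
prediction rather than an ill-defined one. The solve is a Cholesky
factorization of the (symmetric positive-definite) regularized normal
equations; a singular system at λ = 0 raises an error advising a
positive λ.

Two stimulus features are used, each fit in its own model (no joint
multivariate design):

* **audio envelope** — |analytic signal| of the 1–10 Hz band-passed
  waveform, resampled to 250 Hz. The filter-then-Hilbert order is the
  reproduction default; a conventional broadband-Hilbert-then-lowpass
  mode exists behind `mode="broadband"`.
* **word frequency** — a step function equal to `6.33 − log10(wf)` over
  each annotated word and 0 elsewhere, where `wf` is the word's
  SUBTLEX-style corpus frequency (table maximum 6.329, hence the 6.33
  ceiling — a fixed constant, not recomputed from the supplied table).
  Sample assignment is half-open `[onset, offset)` so contiguous words
  never share a sample. Out-of-vocabulary words get `log10(wf) = 0`
  (maximum surprisal) and a loud log message.

### Stimulus and response must share the analysis band

EEG is band-passed to 1–10 Hz before fitting. The raw envelope, however,
is dominated by near-DC power. If only the response is filtered, the
lag-windowed regression absorbs the band-pass filter's long acausal
tails instead of the kernel (numerically: noiseless recovery collapses
from r > 0.99 to r ≈ 0.05). The pipeline therefore applies the identical
zero-phase filter to the regressor (`bandpass_regressor`) before the
design matrix is built. This is a deliberate design choice of this
package and the standard identifiability fix for encoding models.

## Preprocessing

Defaults follow the reproduction values throughout:

| step | rule | default |
|---|---|---|
| band-pass | zero-phase 4th-order Butterworth | 1–10 Hz |
| artifact zeroing | 200-ms window (1-sample step) inside 1-s epochs; epoch zeroed on all channels if any channel's window std exceeds the threshold | 100 µV |
| channel interpolation | inverse-distance mean of the 4 nearest good channels, for channels with more than the threshold of zeroed seconds | 100 s |
| subject gate | drop iff clean data < threshold (strictly less than: exactly 100 s is kept) | 100 s |
| resampling | polyphase anti-aliased | 250 Hz |
| trials | contiguous equal-length segments, remainder to the front | 10 |

Zero-phase filtering is essential because TRF latencies are the
scientific readout; a causal filter would shift them. The window std is
the population (ddof = 0) standard deviation; the threshold is treated
as µV. Zeroed epochs are *retained as zeros* in the modeling (faithful
to the replace-with-zero rule); per-channel zeroed seconds are
attributed to the channels whose own windows crossed the threshold.
Whether the threshold should apply per channel or jointly across
channels is ambiguous in the protocol this reproduces; per-channel
triggering (with all-channel zeroing) is used. A pluggable
`component_hook` slot exists where an ICA-based non-neural component
removal stage would sit; the default is the identity.

Interpolation uses inverse-distance weighting rather than spherical
splines because it is simple and exactly checkable against a brute-force
oracle; positions come from the idealized standard 10–20 montage
(via MNE) or any user-supplied label → (x, y, z) mapping.

## Regularization and evaluation

λ is selected from the fixed 21-point grid 10⁻⁵ … 10⁵ (half-decade
steps) by leave-one-trial-out cross-validation on the training trials:
for each λ and fold, fit on the remaining trials, predict the held-out
trial, and take the grand mean Pearson r over folds and channels
(averaging over channels rather than a single channel is this package's
resolution of an underspecified detail; it is recorded in the run log).
Ties break toward the smaller λ. The individual protocol holds out the
last 20% of trials (configurable), refits on all training trials at the
best λ, and reports per-test-trial correlations averaged. On noiseless
synthetic data the CV optimum is not the smallest grid value: zero-padded
trial edges act as a weak noise source, so λ of order 1% of the Gram
diagonal genuinely maximizes held-out prediction (and recovers the
kernel at r ≈ 0.9999).

**Generic (leave-one-subject-out) models**: for each held-out subject,
the group-level λ maximizes the mean of the other subjects' CV curves;
a TRF is fit on each of those subjects' full data at that λ and the
fits are averaged into one generic model, evaluated on every trial of
the held-out subject. Averaging (rather than pooled regression) is the
default; `method="pooled"` solves the pooled normal equations instead,
with λ scaled by the number of pooled subjects so that identical
subjects give identical answers under both methods.

**Circular-shift null**: the response is circularly rotated by 2 s
within each trial — destroying stimulus-response alignment while
preserving amplitude and spectral statistics — and the identical
train/test protocol is rerun. Per-trial correlations with zero variance
(e.g. fully zeroed segments) are skipped and logged. Evaluation includes
zeroed artifact epochs by default (faithful to the zero-replacement
convention).

## Component features and behavioral statistics

TRF lags in [0, tmax) are divided into four windows: 0–150 ms (N1/P1),
150–250 ms (N2/P2), 250–350 ms (N3/P3) and 350 ms–tmax (late
negativity/positivity); the late window's upper bound is the lag-spec
tmax (1000 ms by default). In each window both the maximum (P) and
minimum (N) weight and their latencies are extracted, ties toward the
earliest lag; windows are half-open so a lag of exactly 150 ms belongs
to the second window.

Group contrasts (NASA-TLX, post-test; both 0–100) use the
pooled-variance Student t-test — df = n₁ + n₂ − 2, which is what the
reproduced df of 55 for 29 + 28 retained subjects implies — not Welch.
Feature-behavior association uses Pearson r with a two-tailed p from
t = r·√((n−2)/(1−r²)) on n−2 df. The report emits one row per
(component, feature kind, channel, stimulus, measure, condition) cell
with uncorrected p-values by default; a Benjamini–Hochberg column is
available behind `bh_correction=True`, and `pooled=True` adds
across-condition rows. All cells are reported; selecting "significant"
rows is left to the user.

## The synthetic-data generator

The generator runs the forward model generatively so every downstream
stage is testable by parameter recovery.

* **Kernels** are sums of Gaussian bumps (amplitude ·
  exp(−4 ln2 (t−latency)²/width²), width = FWHM). Gaussians were chosen
  for closed-form peaks, making amplitude/latency recovery exactly
  checkable. Condition presets place bumps at the latencies where
  grand-average TRF components are observed in this paradigm —
  NP envelope: 100/200/300/500/750 ms with alternating signs;
  P envelope: 400/700 ms; P word-frequency: 100/500/850 ms; NP
  word-frequency: two smooth low-amplitude bumps. Preset widths are
  90–120 ms FWHM so the kernels are essentially band-limited to the
  1–10 Hz analysis band: an estimate from band-passed data can only
  ever be the band-limited kernel, so broader-band ground truth would
  make "recovery" ill-posed rather than merely hard.
* **Stimulus**: the simulated envelope is rectified 1–10 Hz Gaussian
  noise, re-low-passed at 10 Hz (non-negative, < 5% of spectral mass
  above 15 Hz). Simulated word streams draw gamma-distributed word
  durations (shape 4, mean 0.35 s) and exponential gaps (mean 0.15 s)
  from a small synthetic lexicon.
* **EEG**: channel = topography gain × (kernel ⊛ stimulus) × 10 µV
  plus noise. Noise is an even split of a spatially shared 1/f^α source
  (α = 1 by default) and per-channel white noise, scaled per channel so
  var(signal)/var(noise) matches the requested SNR in dB. Optional
  artifact epochs add 200-ms, ~400–500 µV 5 Hz bursts — in-band, so they
  survive the zero-phase band-pass and are caught by the 100 µV rule.
* **Cohorts**: per-subject kernels jitter around the condition preset
  (latency ± 15 ms sd, amplitude cv 0.15, width cv 0.10). Behavioral
  scores are `base + group_offset + 12·(r·z + √(1−r²)·ε)` with z the
  standardized ground-truth component feature across the cohort, making
  the population feature-score correlation exactly the requested r
  (bases 50/60, sd 12, so clipping to [0, 100] is negligible). At most
  one coupling per behavioral measure is supported. All randomness
  flows from one master seed through spawned per-subject substreams.

### What the synthetic data do not show

The generator emulates the *statistical structure* the analysis assumes:
a linear time-invariant stimulus-response mapping, stationary 1/f-plus-
white noise, components with clean Gaussian shapes, and behavioral
scores linearly tied to true component features. Real EEG violates all
of these to some degree (nonlinearity, nonstationarity, ocular/muscle
artifacts with non-trivial spatial structure, latency jitter within a
recording). Passing recovery tests therefore demonstrates that the
*estimator and statistics are correct*, not that effect sizes from real
recordings will match; the reproduced study's headline correlations
depend on its actual recordings and are out of reach of desk-scale
simulation by design.

## Problem sizes used by tests and the acceptance script

Parameter recovery uses one subject at 32 channels, 250 Hz, 300 s,
SNR 0 dB. Null calibration uses 20 subjects at 600 s each: per-subject
null means have a sampling sd that shrinks roughly like 1/duration, and
600 s puts the 20-subject grand mean comfortably inside ±0.02.
Behavioral recovery uses 100 cohorts of 29 + 28 subjects with rendering
disabled (the couplings live in the ground-truth kernels and behavior;
no EEG is needed for that check). The end-to-end CLI demo uses
3 subjects per group at 120 s — the shortest duration that clears the
100-s clean-data gate.

## Numerical details and edge cases

* Lagged design columns are zero-padded where the shift runs off either
  end; rows are never trimmed, so all lags stay aligned.
* Moving-window variance uses cumulative sums per 1-s epoch, clipped at
  zero against cancellation.
* Pearson r of a zero-variance segment is undefined: such trials are
  skipped (NaN-aware means) and logged.
* CSV/TSV floats are written at %.17g and read with round-trip
  precision, so save/load cycles are bit-identical.
* `argmax` tie-breaks (CV λ, component latency) always take the first,
  i.e. smallest-λ / earliest-latency, candidate.

## Known limitations

* No ICA-based artifact classification (hook provided, identity by
  default); no re-referencing; no joint multivariate fits; no decoding
  (backward) models; no spherical-spline interpolation.
* EDF files are read (via MNE) but not written; the canonical container
  is CSV + JSON sidecar.
* The behavioral coupling model is linear with Gaussian noise; one
  coupling per measure.
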