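# Methods

## Analysis model

The package implements a two-stage ("slopes-as-outcomes") multilevel
analysis of SSVEP experiments. Each participant views five 20 s blocks of a
25 Hz pattern-reversal stimulus at increasing brightness (codes −2…2, lux
1–120) and rates each block's unpleasantness on the Gracely Box Scale
(GBS, 0–20). Stage one fits an ordinary least-squares regression per
participant and electrode; stage two regresses the resulting coefficients
across participants on grand-mean-centered moderators (menstrual pain,
somatic symptoms, bladder pain). This is equivalent to a random-slopes
mixed model estimated by unweighted two-step OLS: it assumes the level-1
designs are identical across participants (five blocks, common codes) and
trades a little efficiency for closed-form transparency. Missing or
rank-deficient level-1 cells are dropped listwise with a log entry, and
level-2 degrees of freedom follow the included N (N−1 for intercept-only
models, N−4 with three moderators).

Per-term inference uses model comparison: SS(term) = SSE(model without the
term) − SSE(full model), with the full-model MSE as error term. With one
numerator df this equals the Type III decomposition, F equals the squared
Wald t, `ηp² = SS/(SS + df_den·MSE)`, and CIs are `b ± t(0.975, df_den)·se`.
These identities are asserted on every fit. All tests are two-tailed.
When the level-2 residual variance is exactly zero (noise-free synthetic
data), F is reported as ∞ (or 0 for a zero SS) rather than failing.

The PSD predictor in the moderation analysis is centered within participant
by default, so the level-1 intercept is that participant's mean
unpleasantness collapsed across brightness; grand-mean and no centering are
available via `psd_centering`. Multiplicity over the 31 exploratory
electrodes is handled per (model, term) family with Benjamini–Hochberg
FDR (via statsmodels); the a-priori channel Oz is excluded from the family
and reported unadjusted. Moderator intercorrelations are summarized with
Pearson r and seeded percentile-bootstrap 95% CIs (default B = 2000,
chosen as a conventional bootstrap size; the p-value uses the t transform
of r).

## Signal chain

Fixed order: average-mastoid re-reference → 1 Hz high-pass → downsample to
256 Hz → 60 Hz notch → 2 s epochs with 1 s overlap per block → ±100 µV
rejection → spherical-spline surface Laplacian → Hamming-taper periodogram.

* **High-pass**: Hamming-windowed-sinc FIR, −6 dB at 1 Hz, 2 Hz transition
  band, zero-phase (delay-compensated single pass), delegated to
  `mne.filter.filter_data`.
* **Downsampling**: polyphase resampling (`scipy.signal.resample_poly`,
  64/125) whose built-in FIR handles anti-aliasing; marker indices are
  remapped to the nearest sample. No separate software low-pass is applied.
* **Line noise**: a zero-phase IIR notch (Q = 30) substitutes for
  regression-based line removal; only the 25 Hz bin enters the models and
  it is 35 Hz away from the notch, so the substitution is inconsequential
  (< 1 dB change at 25 Hz, verified in tests).
* **Artifact handling**: component-based artifact removal is out of scope;
  the ±100 µV any-channel any-sample rejection on voltage epochs (before
  the Laplacian) is retained, and the generator's artifact-light default
  stands in for component cleaning.
* **Epoching**: epochs start exactly at the block-onset marker and advance
  by 1 s; the final partial window is discarded, giving 19 epochs per 20 s
  block and 95 per session.

**Surface Laplacian.** Spherical-spline CSD with flexibility m = 4, 50
Legendre terms, smoothing λ = 1e−5 and a 10 cm head radius — the published
defaults of the standard CSD implementation (the analysis itself prescribes
none). The spline system with the flat-spline constraint is solved once per
montage as a dense linear operator; output units are µV/cm². Because each
sample is mapped by one fixed matrix, downstream dB *differences* (slopes)
are invariant to the operator's global scale; absolute dB intercepts are
meaningful only within a fixed montage/parameter set. Electrode positions
are an idealized spherical 10-20 layout generated from the nominal
construction (circumferential ring at 5% steps, intermediate sites as
great-circle midpoints, inferior ring at 108°); real caps deviate from a
sphere, but only relative geometry enters the spline.

**Spectral estimation.** One-sided Hamming-tapered periodogram with density
normalization; 2 s epochs at 256 Hz put 25 Hz exactly on a bin (0.5 Hz
spacing, no zero padding). Per-epoch linear power at the bin is averaged
over a block's kept epochs, then converted to dB (`10·log10`); the
log-then-average alternative is behind a flag. The density normalization
constant cancels in slopes but not intercepts.

## Synthetic data

The generator emulates the study conditions end to end:

* **Cohort** (n = 147 by default): correlated latent Gaussians mapped to
  the target moments — menstrual pain M 62.5, SD 26.1 (VAS 0–100); somatic
  symptoms M 2.37, SD 2.4 (sum capped at a configurable 59, the nominal
  inventory maximum; observed maxima are far lower); bladder pain M 12.2,
  SD 16 (VAS 0–100); correlations 0.28/0.28/0.16 — then truncated at the
  scale bounds. Truncation (≈22% of bladder draws hit 0) biases the
  realized bladder mean upward by ≈2 points and attenuates correlations by
  ≈0.02; this is a documented property of the copula-with-bounds choice,
  tested with tolerance rather than corrected.
* **EEG session**: 34 channels (32 scalp + 2 mastoids) at 500 Hz; five 20 s
  blocks separated by 5 s gaps with 2 s lead-in/out. The SSVEP is a 25 Hz
  sinusoid with a Gaussian spatial falloff from Oz (decay 0.9 rad). Its
  per-block amplitude is set by *empirical calibration*: the whole chain is
  linear, so one noise-free unit-amplitude run measures the chain gain at
  Oz and block amplitudes are scaled to hit the planted dB targets exactly
  (the planted −23.76 dB base yields ≈5 µV at the scalp). Pink (1/f) noise
  (default 10 µV RMS), optional 60 Hz line noise (1 µV) and optional blink
  transients (Gaussian bumps, 150 µV frontal, off by default) are added on
  top.
* **Ratings**: level-1 coefficients are drawn from the planted level-2
  gammas (defaults equal the published point estimates) plus independent
  Gaussian random effects, ratings add residual noise and are clipped to
  0–20 (integer rounding behind a flag; the analysis treats GBS as
  continuous). Random effects for b0/b1/b2 are independent by default —
  their covariance is not identified by the published results.

Noise defaults are derived by matching the published level-2 error terms:
observed MSE ≈ random-effect variance + level-1 sampling variance, which
with five blocks gives residual SD 0.5 GBS, per-block dB noise 3.0,
random-effect SDs (3.85, 0.78, 0.40) and SSVEP base/slope deviations
5.5/0.57 dB — reproducing MSEs near (14.9, 0.66, 0.17) and (31.9, 1.22)
and moderator SEs near the published ones.

What the generator does **not** emulate: physiological artifact
topographies separable by ICA, non-stationary alpha/posterior rhythms,
electrode drift or impedance changes, block-order effects, and any
nonlinearity between lux and cortical response (the planted dB–brightness
relation is exactly linear). Passing recovery tests therefore show the
estimator chain is correct under the assumed data-generating process, not
that real EEG meets those assumptions.

Parameter-recovery and type-I-calibration suites disable the 0–20 clipping:
the estimand under test is the planted linear-model coefficient, and with
censoring active ≈2% of draws clip at 0, attenuating recovered
coefficients by a few percent (an expected property of bounded scales, not
an estimator defect). The clipped configuration remains the study-condition
default everywhere else.

## Problem sizes and numerical choices

Tests and the acceptance script use: full-size cohorts (n = 147) for
statistics-level simulations with 200 Monte-Carlo replicates for recovery
and null calibration; 6 noise-free participants for the full-chain
calibration check (the chain is deterministic, so more add nothing); and
tiny toy fixtures for arithmetic oracles. The spline series uses 50
Legendre terms (entries change < 1e−6 when doubled); the constrained solve
uses a dense augmented-matrix inverse (32 channels — conditioning is
benign); OLS uses `lstsq` with explicit rank checks; brightness codes are
validated to sum to 0 with sum of squares 10; ties in rating clipping and
the strict `>` rejection threshold are fixed conventions tested at the
boundary.

## Limitations

Two-step OLS ignores the differing precision of level-1 estimates (no
FGLS weighting), matching the cited analysis style rather than maximizing
efficiency. The BrainVision writer emits only the float-32 multiplexed
variant. Absolute dB levels depend on the CSD scale convention and the
density normalization; cross-study comparison of intercepts requires
matching both. The bootstrap CI is percentile (not BCa).
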