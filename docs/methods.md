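# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `fetalmove`, and what the synthetic-data experiments do
and do not demonstrate.

## Signal model and the synthetic generator

The generator emulates the statistical structure a tri-axial abdominal
accelerometer presents to a movement detector:

- **Background noise**: i.i.d. Gaussian per axis, standard deviation
  `noise_sigma` (default 0.05 sensor units).
- **Maternal low-frequency component**: a single sinusoid with frequency
  drawn uniformly from 0.2–0.5 Hz (breathing / posture drift), amplitude 0.1
  by default, independent phase per axis.
- **Fetal bursts**: Gaussian-windowed sine tones (envelope σ = duration/6)
  with carrier uniform on 1–20 Hz — the band the wearable-monitoring
  literature attributes to fetal kicks — duration uniform on 0.3–1.0 s, peak
  amplitude 0.2, direction a random 3-vector. Burst onsets follow a Poisson
  process; overlapping bursts are summed.
- **Maternal spikes**: sparse short (0.08 s) Gaussian bumps with peak
  `3·burst_amplitude + 5·noise_sigma`, a deliberately larger confounder the
  classifier must reject. (The spike amplitude is an internal constant
  rather than a config field to keep the config surface minimal.)

Default rates: 22 bursts/min, chosen so that with 2.56 s epochs the
positive-epoch fraction is ≈ 0.7 (`1 − exp(−rate·(epoch + mean burst)/60)`),
matching the class skew a high-recall monitoring setting implies; 2
spikes/min. Amplitudes are stated, not calibrated: no public reference gives
sensor-unit SNR for abdominal recordings, so defaults were fixed once at a
burst-to-noise ratio of 4 and not revisited.

**Ground-truth labels.** An epoch is positive iff a fetal burst overlaps it
by at least 25 % of the burst's own duration; maternal spikes never label an
epoch positive. The threshold makes boundary-straddling bursts label both
epochs — a deliberate, testable convention.

**What the simulator does not capture**: fetal biomechanics, respiration and
cardiac components, sensor drift and saturation, inter-subject variability,
and whatever labeling protocol clinical datasets use. Passing tests
demonstrate the pipeline's internal correctness and its behaviour under the
stated signal model, not clinical performance.

## Kalman preprocessing

The paper-level requirement is recovering a low-amplitude transient from a
noisy background; the state-space model is deliberately minimal — the scalar
local level (A = C = 1, B = 0): a random walk observed in white noise. Per
epoch and per axis:

- **R** (measurement noise) is estimated as
  `(median|Δx| / (0.6745·√2))²` — the MAD of first differences, robust to
  the very transients being detected, floored at 1e-12.
- **Q = q_ratio · R** with `q_ratio = 0.1` by default. The implied
  steady-state gain is ≈ 0.27, i.e. mild smoothing that attenuates the
  20 Hz band edge by ~20 % while cutting noise variance by ~85 %.
- **Initialization**: x̂₀ = first sample, P₀ = R, avoiding burn-in bias on
  short epochs.
- Filtering is applied per epoch, per axis, then the axes are combined into
  the Euclidean norm (a `magnitude_then_filter` mode is one flag away).

The filter is implemented for general matrix parameters (with a fast scalar
path); the innovation covariance reaching exactly zero raises a
degeneracy error naming the step.

## TFWD features

Shape factors use the standard condition-monitoring definitions (waveform =
RMS/mean|x|, crest = peak/RMS, pulse = peak/mean|x|, margin =
peak/(mean √|x|)²); standard deviations are population (ddof 0); quartiles
use linear interpolation; energy is the plain sum of squares. Zero
denominators yield 0 with a degenerate flag rather than NaN.

Spectral features come from the one-sided magnitude spectrum (optional Hann
taper, mean removal by default). "Frequency index" is reported in Hz (not
bin number) so it is invariant to epoch length; ties break toward the lowest
frequency. The sub-maximum is the largest *local* maximum outside the global
peak's 3-bin neighbourhood, which keeps spectral-leakage shoulders from
masquerading as a second component; with no such maximum the pair is (0, 0).
Spectral skewness/kurtosis are moments of the magnitude values (not
frequency-weighted moments — the simpler reading), kurtosis non-excess.
Spectral entropy is Shannon entropy of normalized power divided by
log(n_bins), hence in [0, 1].

Wavelet features use db4 at level 4 with periodization padding; the
orthonormal transform then conserves energy exactly, which the test suite
exploits (subband energy = time-domain energy to 1e-8 relative).

## Gaussian-process Bayesian optimization

- Search space normalized to the unit cube; integer dimensions by continuous
  relaxation + rounding at evaluation. Default bounds:
  N_estimators [10, 300], Max_depth [2, 12], Num_leaves [8, 256],
  Subsample [0.5, 1], Colsample_bytree [0.5, 1], Min_child_samples [2, 30].
- Zero-mean GP after standardizing observed losses; RBF kernel; observation
  noise 1e-6; 1e-10 diagonal jitter in every solve (part of the documented
  numerical contract).
- Length scale θ refit each iteration by log-marginal-likelihood
  maximization over a 25-point log grid (1e-2…10) — no gradient optimizer
  dependency, fully deterministic.
- Acquisition: Expected Improvement (minimization convention, ξ = 0.01),
  maximized over 2048 scrambled-Sobol candidates plus 32 Gaussian local
  perturbations (σ = 0.05) of the incumbent; already-evaluated points are
  skipped in favour of the next-best candidate.
- Budget: 10 Latin-hypercube initial points + 40 EI iterations by default.
  Objective exceptions are recorded as +∞ and the loop continues.

The tuning objective is mean 5-fold stratified log-loss. Inside
cross-validation, tuning is *nested* by default (re-tuned per training
portion) so held-out folds stay untouched; an un-nested mode exists for
replication of protocols that tune once on the full data (and leaks
accordingly).

## Classifier

Training delegates to LightGBM (binary log-loss, leaf-wise growth) pinned to
single-threaded deterministic mode; `subsample_freq=1` is set whenever
subsample < 1 so row subsampling actually engages. Default hyperparameters
are the Bayesian-optimization incumbent of the reference configuration
(51 trees, depth 5, 63 leaves, subsample 0.8863, colsample 0.9079,
min_child_samples 8); learning rate 0.1 is a documented default, not a tuned
value. Prediction validates the feature schema (names and order) and reports
an explicit column diff on mismatch.

The split-gain reference functions define the GOSS-adjusted gain with
full-data counts in the denominators (only gradient sums are subsampled and
reweighted by (1−a)/b), so the GOSS gain reduces *exactly* to the plain gain
at a = 1. The (1−a)/b correction makes the reweighted gradient sums unbiased
for the full sums; the squared gain statistic additionally carries a
second-order sampling term of order Var(sum)/(n_l·n₀), so Monte-Carlo
centring checks are run on fixtures where the kept large-gradient instances
lie on one side of the threshold and that term is negligible.

## Evaluation conventions

Positive class is "fetal movement", coded 1 internally and stated in every
report (field datasets sometimes code movement as 0; re-coding belongs at
the I/O boundary). Hard labels threshold probabilities at 0.5. Folds are
stratified with a fixed seed; AUC uses the rank (Mann–Whitney) formulation
via scikit-learn. Degenerate metric cases (no predicted positives, no actual
positives) return 0 with a flag rather than NaN.

## Problem sizes

Tests and the acceptance script run on synthetic recordings of 128–512 s
(50–200 epochs), Monte-Carlo oracles at 10⁴–10⁶ draws, and optimizer
benchmarks of 20–50 seeded repeats — sizes chosen to make the stochastic
assertions statistically comfortable while keeping a full run in seconds on
one core. The end-to-end high-SNR check uses a burst-to-noise amplitude
ratio of 10 and asserts ≥ 0.90 median accuracy over three seeds; the
default-condition (ratio 4) pipeline typically lands in the low 90s as well.

## Known limitations

- The local-level filter is a smoother, not a matched detector; at very low
  SNR its benefit over raw magnitude features is within noise (the ablation
  test asserts only that it does not hurt).
- Continuous-relaxation rounding can propose duplicate integer
  configurations; the proposal step redraws, and a fully-integer space can
  be exhausted (raised explicitly).
- Real recordings enter through the delimited-text reader
  (`time,x,y,z` plus an optional events sidecar); per-epoch labels for data
  without an event log must be supplied separately — the pipeline does not
  guess annotations.
- No multiclass support; no extended/unscented filters; no alternative
  boosting backends.
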