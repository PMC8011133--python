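# Methods

## Signals and conventions

Two tri-axial accelerometers, one at the back of the head and one over the
third lumbar vertebra (lower trunk), record level walking at 148 Hz in
units of g. Axes follow the sensor frame: ML (x, right), AP (y, forward),
VT (z, up); a static, correctly aligned sensor reads +1 g on VT. Subjects
walk a 20 m walkway; a timing gate measures the duration of the middle
10 m of steady walking, and a subject's trial set is considered
unrepeatable — and is dropped — when the coefficient of variation of those
durations exceeds 5 %. The 5 % rule is read as relative SD (SD/mean);
an absolute SD threshold would carry units and make the rule depend on
walking speed.

## Preprocessing

Gravity is removed by subtracting the per-axis mean over the analysed
segment. Without gyroscopes or magnetometers there is no attitude
estimate to rotate gravity out with; mean subtraction is the minimal
de-gravitation consistent with the ±1 g static calibration, and it also
centres the ML/AP axes, which the autocorrelation metrics assume. The
signal is then low-pass filtered with a 2nd-order Butterworth at 22 Hz,
applied forward and backward (`sosfiltfilt`). Zero-phase filtering
preserves step-peak timing at the cost of squaring the magnitude
response; the effective amplitude gain at frequency f is |H(f)|² of the
designed digital filter. The two operations are both linear with unit DC
gain and commute up to the small per-axis constant that filter edge
transients contribute to the sample mean.

## Step detection and temporospatial variables

Gait cycles are delimited by peaks of the vertical lower-trunk
acceleration: one peak per step, two steps per stride. The step period is
first estimated from the dominant periodogram frequency in the 0.5–4 Hz
locomotion band (a signal whose in-band maximum is less than 20× the
median periodogram level is rejected as "no gait" — a raw periodogram of
white noise tops out near ln(n_bins)× its median, far below that).
Peaks are then selected with minimum separation of half the step period
and prominence at least 0.3× the signal SD; both thresholds are
configurable, and were chosen so that incidental oscillations between
heel strikes are not counted.

Temporospatial variables: walking speed = 10 m / timed duration; step
length = 10 m / steps in the timed window (in cm); cadence = steps per
minute in the timed window; step-timing variability = sample SD (n−1) of
successive gait-cycle durations over the whole trial. "Gait cycle" is
taken as the stride — the alternate-peak interval, including the
overlapping intervals starting at each step — because cycles are defined
by acceleration peaks and a stride is the natural cycle of gait; the
step-interval reading is available via `cycle="step"`.

## Stability metrics

All six metrics are computed per axis and sensor on the preprocessed
signal.

**Harmonic ratio.** The stride frequency is measured from the detected
events (1/mean stride duration); an autocorrelation-based fallback takes
the lag of the second autocorrelation peak (the first being the step lag
on the step-periodic VT/AP axes it is intended for). The signal is
trimmed to a whole number of strides and amplitudes A₁..A₂₀ are evaluated
by discrete Fourier sums at exact multiples of the stride frequency —
evaluating at exact harmonics over whole strides keeps spectral leakage
out of the even/odd split, which windowed FFT bins would contaminate.
Twenty harmonics (10 even + 10 odd) is the convention of the
harmonic-ratio literature. VT/AP use ΣA_even/ΣA_odd; ML uses the
inverted ratio because ML alternates sign between left and right steps,
putting its in-phase content on the odd stride harmonics. The inversion
is controlled by `ml_inverted` (default true); a denominator below
10⁻¹² g raises a degenerate-harmonics error rather than returning an
arbitrary cap.

**Regularity and symmetry.** The unbiased autocorrelation coefficient
r(τ) = [Σ x_t x_{t+τ}/(n−τ)] / [Σ x_t²/n] is normalised to r(0)=1; step
regularity SR1 is its maximum within ±25 % of the nominal step lag,
stride regularity SR2 within ±25 % of the stride lag. The windows
tolerate within-trial cadence drift. Gait symmetry is
min(|SR1|,|SR2|)/max(|SR1|,|SR2|), which is order-invariant and confined
to [0, 1]; absolute values keep a rare negative step-lag correlation from
producing a negative "symmetry".

**Gait variability.** Welch PSD with a window of four stride periods,
50 % overlap and mean detrending; the dominant peak is the PSD maximum in
0.5–4 Hz and its full width at half maximum is found by linear
interpolation to the half-power crossings. The width is reported in Hz;
a dimensionless variant (FWHM ÷ peak frequency) is available as
`GaitVariability.normalized`, since clinical reports sometimes normalise
the width and the plain-Hz value depends on the spectral-estimation
window. A width whose half-power crossing falls outside the spectrum is
flagged `truncated`.

**Feature vector.** 5 temporospatial + 6 metrics × 3 axes × 2 sensors =
41 named values per trial (`trunk_vt_rms`, `head_ap_sr1`, …). Per-subject
features are the NaN-aware mean over the subject's valid trials —
averaging before classification keeps trial-level information from
leaking across cross-validation folds. A metric that fails on some axis
is recorded as NaN with a reason flag, never silently dropped.

## Cohort statistics

Each feature is screened with a Kolmogorov–Smirnov test; because the
comparison normal has its parameters estimated from the sample, the
Lilliefors variant is the default (plain KS against the fitted normal via
`method="fitted"`). Features rejected at α = 0.05 with positive sample
skewness are log₁₀-transformed; a skewed feature containing non-positive
values is left untransformed and flagged. Walking-stability features are
then adjusted for walking speed: OLS of feature on speed over all
subjects pooled, keeping residual + grand mean. The residualisation is
idempotent and leaves exactly zero sample correlation with speed. Group
differences use classic fixed-effects one-way ANOVA
(F = MS_between/MS_within); healthy-vs-patients and the three-DHI-subgroup
comparison are run as separate analyses. No multiple-testing correction
is applied by default, matching per-feature reporting practice.

## Severity model

Features are z-scored and reduced to 4 principal components, with a
deterministic sign convention (each component's largest-magnitude loading
positive). The classifier is a one-vs-rest linear-kernel SVM (C = 1),
chosen as the only multi-class scheme consistent with reporting one AUC
per group; continuous decision scores feed per-class ROC curves. AUC is
computed from midranks (probability a positive outscores a negative, ties
½), identical to the trapezoidal area under the empirical ROC.

Evaluation is repeated stratified 5-fold cross-validation, 10 repeats by
default, fully seeded. Standardisation and PCA are fit on the four
training folds only and applied to the held-out fold; fitting them on the
pooled data before splitting (`leak_mode=True`) is provided for
comparison with analyses that reduce before cross-validating. Folds in
which a class is absent from the held-out set contribute no AUC for that
class; missing feature values are median-imputed within training folds
and the report is flagged.

## Synthetic gait simulator

The simulator is the package's test bed and demo cohort; it emulates the
signal structure the metrics measure, not the biomechanics that produce
it.

A trial is built from a piecewise-linear stride phase: each stride spans
2π but its wall-clock duration is drawn as N(stride_time_mean,
stride_time_jitter_sd), so timing jitter genuinely broadens the spectral
lines and decays the autocorrelation instead of being painted onto an
otherwise fixed-frequency signal. Each axis is a sum of stride-frequency
harmonics with configurable amplitudes: VT/AP even-dominated (the step
pattern repeats each half-stride), ML odd-dominated. Left/right
asymmetry scales the first half of each stride cycle by (1+a) and the
second by (1−a) on VT/AP, which transfers even-harmonic power onto odd
harmonics — exactly the quantity HR and the symmetry index measure. VT
carries the +1 g gravity offset; white Gaussian sensor noise is added per
axis from a sensor-specific stream, so the head and trunk trials of one
pass share stride timing but not noise.

Defaults describe self-paced healthy walking: 1.0 s stride time
(cadence 120 steps/min), 1.2 m/s speed, trunk axis RMS ≈ 0.19/0.08/0.09 g
(VT/AP/ML), head amplitudes 0.8× trunk on VT/AP and 1.1× on ML, 0.02 g
noise, 30 s trials at 148 Hz. Cohort groups are severity-graded — speed
1.20/1.13/1.10/1.05 m/s, jitter 16/19/23/29 ms, asymmetry
0.04/0.10/0.17/0.27, amplitude scale 1.00/0.92/0.87/0.80 for
healthy/mild/moderate/severe — with between-subject spread around each
group mean and per-trial variation of the timed duration (CV ≈ 1.2 %,
inside the 5 % validity rule). DHI scores are drawn uniformly within the
stage's range; healthy subjects score 0. No per-subject raw signal
characteristics of any clinical cohort are available to calibrate
against, so these values are illustrative: chosen once for plausible
magnitudes and a clean severity gradient. What passing tests show is
that the pipeline recovers injected structure (asymmetry, jitter,
severity ordering) from signals with this harmonic anatomy — not that it
reproduces any particular clinical cohort's group means, and real
recordings additionally contain turning segments, attitude drift,
non-stationary cadence and non-white sensor noise that the simulator
deliberately omits.

## Problem sizes

The bundled demo and the acceptance script run the full study shape
(27 healthy + 12/9/6 patients × 6 trials × 2 sensors). Seed-sweep
checks (parameter recovery, event detection, classifier ordering) use 20
seeds; the severity-ordering sweep uses reduced cohorts of 8/6/6/6
subjects with 2 trials each, and ANOVA calibration uses 10,000 simulated
null datasets of 3 groups × 10 — sizes chosen to estimate each property
stably at desk scale.

## Known limitations

- Mean-subtraction de-gravitation leaves any attitude misalignment inside
  the ML/AP signals; no sensor-to-body alignment correction is applied.
- The autocorrelation stride-frequency fallback assumes a step-periodic
  axis (VT/AP); on strongly asymmetric or ML signals, prefer the
  event-based estimate.
- The FWHM gait-variability value depends on the Welch window length
  (four stride periods); compare values only across equal configurations.
- The simulator's groups differ only through the graded parameters above;
  demographic covariates are decorative and carry no signal.
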