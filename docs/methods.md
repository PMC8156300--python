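# Methods

## Signal model and index definitions

The input is a pair of uniformly sampled band-excursion signals,
rib cage `rc(t)` and abdomen `abd(t)`, in arbitrary calibrated units.
No volume calibration is attempted: every index the pipeline reports is
a phase angle or an amplitude ratio, and is therefore invariant to
rescaling both channels by any positive constant (this invariance is
enforced by tests).

All windowed indices use sliding windows of `window_s = 30 s` with
`step_s = 5 s` (defaults, configurable). Each window is linearly
detrended and Hann-tapered before any FFT. Rationale for the defaults:
30 s holds at least five breath cycles down to 10 breaths/min, giving a
stable cross-spectral estimate, while a 5 s step yields ~31 phase
samples over a 3-minute recording — enough to resolve the phase
distribution downstream.

**Phase difference.** For each window, both channels are FFTed and the
dominant breathing bin is the maximizer of the *product* of the two
power spectra within 0.05–2 Hz (3–120 breaths/min). Using the product
favors a frequency with energy in both compartments when the channels
peak at different bins. The phase is the argument of the cross-spectrum
`FFT(rc) · conj(FFT(abd))` at that bin, folded to [0°, 180°]:
asynchrony is treated as an unsigned magnitude, matching how the ICP
summary and the reference envelopes are read. On noise-free sinusoids
the estimator recovers the generated lag to well under 1° across the
full 0–180° range.

**Amplitudes.** The "absolute amplitude" of a detrended window is
estimated as `sqrt(2) · RMS`, which equals the sinusoid amplitude
exactly for a pure tone and is robust to single-sample spikes.
Half peak-to-peak is available as a config alternative
(`amplitude_method="ptp"`), but it is biased upward by additive noise
(the extreme of thousands of noise samples exceeds several standard
deviations), so RMS is the default.

**%RC** = `100 · A_rc / (A_rc + A_abd)` per window. The mirrored
abdominal share satisfies %RC + %ABD = 100 identically.

**LBI** = `(A_rc + A_abd) / A_sum` per window, where `A_sum` is the
amplitude of the detrended *sum* signal `rc + abd`. If the compartments
move in unison the numerator equals the denominator and LBI = 1; any
phase offset reduces `A_sum`, so LBI ≥ 1 by the triangle inequality.
For two equal unit sinusoids at 90° the sum has amplitude √2, so
LBI = 2/√2 ≈ 1.414. Numerical-noise excursions below 1 are clipped to
1; perfect cancellation (equal amplitudes at exactly 180°) is reported
as an `inf` sentinel and flagged abnormal downstream.

**Respiratory rate** is 60 × the dominant in-band frequency of the
summed detrended signal, refined by parabolic interpolation on log
power across the three bins around the spectral peak (sub-bin
resolution, ~0.02 breaths/min on 3-minute recordings). The rate is
undefined when the summed signal is flat — including the degenerate
equal-amplitude 180°-lag case — and the estimator raises an error
rather than guessing.

## Inverse cumulative percentage (ICP)

"Inverse cumulative percentage" is defined here as the empirical
survival function of the windowed phase series in percent:

    icp(θ) = 100 · #{windows with phase ≥ θ} / #windows,

on an integer grid θ = 0, 1, …, 180°. This reading makes the curve
start at 100%, decrease monotonically, and lets the median be read at
the 50% crossing; the quartiles at the 75% and 25% crossings. The
marker for percentage q is the **largest grid angle whose ICP strictly
exceeds q**. This tie rule is deterministic on the step functions the
ICP produces, and for grid-valued data it coincides with the type-1
empirical quantile (`numpy.quantile(..., method="inverted_cdf")`) —
both facts are property-tested against brute-force counting.

Reference envelopes over a labelled cohort are pointwise min–max bands
per class by default; percentile bands (e.g. 5–95%) are available via
`build_envelopes(..., band="percentile")` and are less sensitive to a
single extreme subject. Min–max was chosen as the default because the
training cohorts in view are small (tens of subjects), where trimming
would discard a substantial fraction of the information.

ICP feature vectors for the classifier sample the curve every 5°
(p = 37 predictors, configurable). With cohorts of ~20 subjects this is
deliberately over-parameterized, which is precisely why the classifier
is penalized.

## Elastic-net logistic classification

Labels are encoded normal = 0, abnormal = 1. The model is logistic
regression with the elastic-net penalty

    (1/n) Σ loss + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ],

with mixing weight α = 0.5 by default (the conventional midpoint; fully
configurable). Features are standardized internally before
penalization — the ICP predictors share a 0–100 scale but have very
different variances across angles — and coefficients are mapped back to
the original scale for reporting and prediction.

The λ path is log-spaced (40 points by default) downward from the
smallest λ at which all coefficients vanish. For each λ, stratified
k-fold cross-validation (k = 10 by default, fold assignment seeded)
computes the **misclassification error** — not deviance, since the
selection curve is read in error units. λ is selected by the
one-standard-error rule: the largest λ whose mean CV error is within
one standard error of the minimum, i.e. the most parsimonious model
statistically indistinguishable from the best. A plain min-error rule
is available. The model is then refit on all data at the selected λ.

Numerics: fits use scikit-learn's saga solver with the mapping
C = 1/(n·λ), tolerance 1e-6, and a pinned internal shuffle seed so the
whole procedure is bit-deterministic given (X, y, seed). λ = 0 falls
back to an unpenalized lbfgs fit; tests verify that endpoint against an
independent IRLS implementation to 1e-4. Prediction thresholds the
logistic probability at 0.5 (configurable).

## Flag rules

- **Deviation rule** (RR, %RC, LBI): abnormal iff
  |value − healthy mean| > 0.20 · healthy mean. Boundary values
  (exactly ±20%) are normal. Two-sided by default.
- **Phase**: the same rule but one-sided *above* by default — only a
  lag larger than the healthy mean is pathological. Configurable to
  two-sided.
- **ETCO₂**: normal iff within 35–45 mmHg inclusive.
- **SpO₂**: normal iff strictly greater than 95%.
- Missing values (absent vitals, age outside the reference table, NaN)
  produce `unavailable`, never an exception.

The shipped healthy reference table
(`src/taarip/data/reference_ranges.json`) contains **illustrative
placeholder values** — textbook-plausible age-banded respiratory rates,
%RC ≈ 50, LBI slightly above 1, small phase means — and is meant to be
replaced with locally validated norms. An infinite mean LBI (perfect
cancellation) is always flagged abnormal.

## Synthetic generator

The generator emulates two study conditions:

- *normal* — quiet tidal breathing: phase lag drawn from [0°, 30°],
  roughly equal compartment amplitudes (each uniform in [0.8, 1.2]);
- *abnormal* — asynchronous breathing of the kind induced by an
  external resistive load: lag from [60°, 180°], unequal amplitudes
  (RC in [0.4, 1.2], ABD in [0.8, 1.6]).

Both conditions share: rate 12–25 breaths/min, additive white noise
with sd 0.01–0.05 (1–5% of a unit amplitude), linear baseline drift up
to ±0.1 units/min, and breath-to-breath rate variability modelled as an
Ornstein–Uhlenbeck perturbation of the instantaneous rate (sd 0.2–1
breaths/min, 10 s correlation time) — naturalistic variability without
breath-segmentation artifacts. Default recordings are 180 s at 50 Hz,
matching a ~3-minute bedside session sampled comfortably above the
breathing band.

Asynchrony is modelled as a **pure phase lag plus amplitude
imbalance**, not as airway mechanics: relative RC/ABD motion changes
are nonspecific to the obstructive-vs-restrictive cause, so a
kinematic surrogate suffices for training and validating the pipeline.
Healthy thoraco-abdominal delay is near zero; the abnormal lag interval
is a configurable stand-in since no empirical lag distribution for
loaded breathing is available to this package. The gap between the two
intervals (30–60°) makes the default cohorts separable by construction,
which is what the classifier-recovery tests exploit.

Randomness: all draws come from NumPy's PCG64 (`default_rng`). A cohort
uses one master seed; each subject's generator seed and parameters are
drawn from the master stream in subject order, so cohorts are
reproducible subject-by-subject.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: band slippage and motion artifacts,
non-sinusoidal breath shapes (inspiratory/expiratory asymmetry), sighs,
apneas, coughs, time-varying asynchrony within a recording, and any
physiological coupling between rate, depth and lag. Results on real
patient recordings depend on signal quality screening
(`validate_recording`, Konno–Mead loop review) that synthetic data
never triggers.

## Problem sizes

The test suite and the acceptance script run on 180 s recordings at
50 Hz (9001 samples), cohorts of 10 + 10 subjects for classifier
recovery (repeated over 10 master seeds with fresh 10 + 10 test
cohorts), 100-recording fuzz suites for the index invariants, and 1000
random series for the ICP oracle. These sizes were chosen to exercise
every code path at the same recording length and window count a
3-minute clinical session produces.

## Known limitations

- The phase estimator returns a single dominant-frequency phase per
  window; multi-frequency breathing (e.g. periodic breathing) is
  summarized by whichever component dominates both channels.
- The folded phase discards the sign of the lag (which compartment
  leads); the signed value is available from the cross-spectrum but not
  propagated into the ICP.
- RR estimation fails on (near-)perfectly cancelling channels; callers
  analyzing suspected paradoxical breathing should treat an RR error as
  a finding, not a bug.
- The classifier's accuracy claims hold on the synthetic cohorts
  defined above; no claim is made about transfer to any patient
  population without retraining on representative recordings.
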