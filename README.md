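# taarip

Automated assessment of **thoracic-abdominal asynchrony (TAA)** from
dual-band respiratory inductance plethysmography (RIP) signals.

RIP measures breathing noninvasively through two elastic bands — one
around the rib cage (RC), one around the abdomen (ABD) — whose
inductance tracks the cross-sectional area of each compartment. In
healthy tidal breathing the two compartments move almost synchronously
and contribute roughly equally to tidal volume; pulmonary dysfunction
shows up as a growing phase lag between them (up to fully paradoxical
motion), an imbalanced compartment split, and extra breathing effort.
Because the test requires no voluntary maneuver, it suits children and
patients who cannot perform spirometry.

`taarip` implements the full analysis chain:

1. **Indices** (per sliding window, FFT-based):
   - *phase difference* φ ∈ [0°, 180°] — the cross-spectral phase of
     RC vs. ABD at the dominant breathing frequency (0° synchronous,
     180° paradoxical);
   - *%RC* = 100·A_RC / (A_RC + A_ABD) — the rib-cage share of the
     combined excursion (≈50% in quiet breathing);
   - *LBI* (labored breathing index) = (A_RC + A_ABD) / A_(RC+ABD) —
     the ratio of the as-if-in-unison amplitude sum to the amplitude of
     the recorded sum signal; exactly 1 when the compartments are in
     phase, growing (toward ∞ at perfect cancellation) with asynchrony;
   - *respiratory rate* from the dominant spectral peak of the summed
     signal.
2. **ICP** (inverse cumulative percentage): the survival function of
   the windowed phase series — for each angle θ, the percentage of the
   recording spent at phase ≥ θ — with median/quartile markers and
   normal/abnormal reference envelopes built from a labelled cohort.
3. **Classifier**: an elastic-net-regularized logistic model
   ŷ = σ(β̂₀ + x₁β̂₁ + ⋯ + x_pβ̂_p) on ICP values sampled every 5°
   (p = 37), with the penalty chosen by 10-fold cross-validation and
   the one-standard-error rule.
4. **Report**: per-subject normal/abnormal/unavailable flags per index
   (±20%-of-healthy-mean deviation rules, ETCO₂ 35–45 mmHg range,
   SpO₂ > 95%) plus the classifier verdict.
5. **Synthetic generator**: seeded two-band breathing signals with
   controlled rate, amplitude split, phase lag, drift, noise and
   breath-to-breath rate variability, emulating quiet tidal breathing
   and resistive-load-like asynchronous breathing, so the whole
   pipeline is testable without patient data.

## Worked example

```python
import numpy as np
import taarip as T

# a markedly asynchronous synthetic subject: 130 deg lag, ABD-dominant
p = T.BreathingParams(rate_bpm=22.0, amp_rc=0.6, amp_abd=1.3,
                      phase_lag_deg=130.0, noise_sd=0.04,
                      rate_jitter_sd=0.5, duration_s=180.0, seed=7)
rec = T.generate_breathing(p)
series = T.compute_indices(rec)          # 30 s windows, 5 s step
print(f"RR    = {series.rr_bpm:.1f} breaths/min")
print(f"phase = {series.mean_phase_deg:.1f} deg")
print(f"%RC   = {series.mean_rc_percent:.1f} %")
print(f"LBI   = {series.mean_lbi:.2f}")

curve = T.compute_icp(series.phase_deg)
print(f"ICP median = {curve.median_deg:.0f} deg "
      f"(q25 {curve.q25_deg:.0f}, q75 {curve.q75_deg:.0f})")

# train on a labelled synthetic cohort, then classify the subject
spec = T.CohortSpec(n_normal=10, n_abnormal=10, seed=1)
X, y = [], []
for r, lab in T.generate_cohort(spec):
    s = T.compute_indices(r)
    X.append(T.icp_features(T.compute_icp(s.phase_deg)))
    y.append(lab)
model = T.fit_elastic_net(np.array(X), y, T.DEFAULT_FEATURE_GRID_DEG, seed=1)
prob, label = T.predict(model, T.icp_features(curve))
print(f"classifier: p(abnormal) = {prob:.3f} -> {label}")
```

Output:

```
RR    = 21.9 breaths/min
phase = 129.9 deg
%RC   = 31.7 %
LBI   = 1.85
ICP median = 129 deg (q25 129, q75 130)
classifier: p(abnormal) = 0.569 -> abnormal
```

The estimated phase recovers the generated 130° lag; %RC well below
50% reflects the abdominal-dominant amplitude split (0.6 vs 1.3); LBI
of 1.85 quantifies the efficiency loss from the asynchrony; and the
ICP-based classifier, trained only on the synthetic cohort, labels the
subject abnormal.

## Command line

```sh
taa simulate --spec spec.json --out cohort/   # synthetic cohort + labels + vitals
taa analyze rec.csv --window 30 --step 5 --out indices.csv
taa icp indices.csv --out icp.csv
taa train --features features.csv --labels labels.csv --seed 7 --out model.json
taa predict --model model.json --features features.csv --out predictions.csv
taa report --indices indices.csv --vitals vitals.json --model model.json --out report.json
taa run --config config.json                  # full seeded pipeline
```

## Documentation

See `docs/methods.md` for the model, the estimator choices, the
synthetic generator's assumptions, and known limitations.
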