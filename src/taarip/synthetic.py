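"""Seeded synthetic two-band breathing recordings.

Asynchrony is modelled as a pure phase lag of the abdominal channel
behind the rib-cage channel plus an amplitude imbalance — not as airway
mechanics.  Relative RC/ABD motion changes are nonspecific to the
obstructive-vs-restrictive cause, so a lag-plus-imbalance surrogate is a
reasonable stand-in for resistive-load breathing when training and
testing the downstream pipeline.

Both channels share one instantaneous breathing rate; optional
breath-to-breath variability is an Ornstein–Uhlenbeck-smoothed
perturbation of that rate, giving naturalistic drift without breath
segmentation artifacts.  All randomness comes from NumPy's PCG64
generator, fully determined by the integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .signal_io import BandRecording, VitalSigns, DEFAULT_FS

logger = logging.getLogger("taarip")

NORMAL = "normal"
ABNORMAL = "abnormal"

#: Phase-lag sampling intervals (degrees) for labelled cohorts.  Healthy
#: thoraco-abdominal delay is near zero; the abnormal interval is a
#: configurable stand-in chosen to be separable with a margin.
DEFAULT_NORMAL_LAG_DEG = (0.0, 30.0)
DEFAULT_ABNORMAL_LAG_DEG = (60.0, 180.0)

#: Correlation time (s) of the rate-jitter process; a few breaths long.
RATE_JITTER_TAU_S = 10.0


@dataclass
class BreathingParams:
    """Generator settings for one synthetic recording.

    rate_bpm is the mean breathing rate; phase_lag_deg in [0, 180] is how
    far the abdomen lags the rib cage within the breathing cycle (0 =
    synchronous, 180 = paradoxical).  noise_sd is additive white noise
    per channel, drift_per_min a shared linear baseline drift, and
    rate_jitter_sd the standard deviation of the smoothed rate
    perturbation, all in the same arbitrary units as the amplitudes.
    """

    rate_bpm: float = 15.0
    amp_rc: float = 1.0
    amp_abd: float = 1.0
    phase_lag_deg: float = 0.0
    noise_sd: float = 0.0
    drift_per_min: float = 0.0
    rate_jitter_sd: float = 0.0
    duration_s: float = 180.0
    fs: float = DEFAULT_FS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_bpm <= 0:
            raise ValueError("rate_bpm must be positive")
        if self.amp_rc < 0 or self.amp_abd < 0 or self.amp_rc + self.amp_abd == 0:
            raise ValueError("amplitudes must be non-negative and not both zero")
        if not 0 <= self.phase_lag_deg <= 180:
            raise ValueError("phase_lag_deg must lie in [0, 180]")
        if self.noise_sd < 0 or self.rate_jitter_sd < 0:
            raise ValueError("noise_sd and rate_jitter_sd must be non-negative")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")


@dataclass
class CohortSpec:
    """Sampling plan for a labelled cohort of synthetic subjects.

    Parameter ranges are ``{field: (lo, hi)}`` dictionaries; each
    subject's :class:`BreathingParams` fields are drawn uniformly from
    them.  Unlisted fields keep the BreathingParams defaults.
    """

    n_normal: int = 10
    n_abnormal: int = 10
    normal_param_ranges: dict = field(default_factory=dict)
    abnormal_param_ranges: dict = field(default_factory=dict)
    duration_s: float = 180.0
    fs: float = DEFAULT_FS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("cohort sizes must be non-negative")
        for ranges in (self.normal_param_ranges, self.abnormal_param_ranges):
            for key, (lo, hi) in ranges.items():
                if lo > hi:
                    raise ValueError(f"interval for {key} is not well-ordered: ({lo}, {hi})")


def _default_ranges(label: str) -> dict:
    """Quiet-tidal vs. resistive-load-like condition parameter ranges."""
    common = {
        "rate_bpm": (12.0, 25.0),
        "noise_sd": (0.01, 0.05),
        "drift_per_min": (-0.1, 0.1),
        "rate_jitter_sd": (0.2, 1.0),
    }
    if label == NORMAL:
        # near-synchronous, roughly equal compartment contributions
        return {
            **common,
            "amp_rc": (0.8, 1.2),
            "amp_abd": (0.8, 1.2),
            "phase_lag_deg": DEFAULT_NORMAL_LAG_DEG,
        }
    # asynchronous with unequal compartments
    return {
        **common,
        "amp_rc": (0.4, 1.2),
        "amp_abd": (0.8, 1.6),
        "phase_lag_deg": DEFAULT_ABNORMAL_LAG_DEG,
    }


def generate_breathing(p: BreathingParams) -> BandRecording:
    """Synthesize one dual-band recording from :class:`BreathingParams`.

    ``rc(t) = amp_rc * sin(theta(t)) + drift(t) + noise`` and
    ``abd(t) = amp_abd * sin(theta(t) - lag) + drift(t) + noise`` where
    ``theta`` integrates the (optionally jittered) instantaneous rate.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs)) + 1
    t = np.arange(n) / p.fs
    dt = 1.0 / p.fs

    rate_bpm = np.full(n, p.rate_bpm)
    if p.rate_jitter_sd > 0:
        # Ornstein-Uhlenbeck: x' = -x/tau + sqrt(2/tau)*sd*dW
        x = np.empty(n)
        x[0] = rng.normal(0.0, p.rate_jitter_sd)
        a = np.exp(-dt / RATE_JITTER_TAU_S)
        innov_sd = p.rate_jitter_sd * np.sqrt(1.0 - a * a)
        shocks = rng.normal(0.0, innov_sd, size=n - 1)
        for i in range(1, n):
            x[i] = a * x[i - 1] + shocks[i - 1]
        rate_bpm = np.maximum(rate_bpm + x, 0.1 * p.rate_bpm)

    theta = 2.0 * np.pi * np.cumsum(rate_bpm / 60.0) * dt
    lag = np.deg2rad(p.phase_lag_deg)
    drift = p.drift_per_min * t / 60.0

    rc = p.amp_rc * np.sin(theta) + drift
    abd = p.amp_abd * np.sin(theta - lag) + drift
    if p.noise_sd > 0:
        rc = rc + rng.normal(0.0, p.noise_sd, size=n)
        abd = abd + rng.normal(0.0, p.noise_sd, size=n)

    return BandRecording(subject_id=f"synth-{p.seed}", fs=p.fs, t=t, rc=rc, abd=abd)


def _draw_params(rng: np.random.Generator, ranges: dict, spec: CohortSpec, seed: int) -> BreathingParams:
    drawn = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
    return BreathingParams(duration_s=spec.duration_s, fs=spec.fs, seed=seed, **drawn)


def generate_cohort(spec: CohortSpec) -> list[tuple[BandRecording, str]]:
    """Generate ``n_normal + n_abnormal`` labelled recordings.

    One master seed; each subject gets a sub-seed drawn from the master
    PCG64 stream, so cohorts are reproducible subject-by-subject.
    Normal subjects draw their phase lag from a low interval, abnormal
    from a high one; overlapping intervals are permitted but logged since
    they weaken separability.
    """
    normal_ranges = {**_default_ranges(NORMAL), **spec.normal_param_ranges}
    abnormal_ranges = {**_default_ranges(ABNORMAL), **spec.abnormal_param_ranges}
    n_lo, n_hi = normal_ranges["phase_lag_deg"]
    a_lo, a_hi = abnormal_ranges["phase_lag_deg"]
    if max(n_lo, a_lo) <= min(n_hi, a_hi):
        logger.warning(
            "normal and abnormal phase-lag intervals overlap: [%g, %g] vs [%g, %g]",
            n_lo, n_hi, a_lo, a_hi,
        )

    master = np.random.default_rng(spec.seed)
    out: list[tuple[BandRecording, str]] = []
    for i in range(spec.n_normal + spec.n_abnormal):
        label = NORMAL if i < spec.n_normal else ABNORMAL
        ranges = normal_ranges if label == NORMAL else abnormal_ranges
        sub_seed = int(master.integers(0, 2**31 - 1))
        params = _draw_params(master, ranges, spec, sub_seed)
        rec = generate_breathing(params)
        rec.subject_id = f"{label}-{i:03d}"
        out.append((rec, label))
    return out


def generate_vitals(label: str, age_years: float, seed: int) -> VitalSigns:
    """Draw a vital-sign summary consistent with the breathing label.

    Normal subjects always fall in the healthy ranges (ETCO2 35–45 mmHg,
    SpO2 > 95%, age-typical RR); abnormal subjects may fall outside them.
    """
    if age_years < 0:
        raise ValueError("age_years must be non-negative")
    rng = np.random.default_rng(seed)
    # age-typical resting respiratory rate, declining toward adulthood
    rr_typical = 30.0 - 18.0 * min(age_years, 18.0) / 18.0
    if label == NORMAL:
        rr = float(rng.uniform(0.9, 1.1) * rr_typical)
        etco2 = float(rng.uniform(36.0, 44.0))
        spo2 = float(rng.uniform(96.0, 99.5))
        hr = float(rng.uniform(60.0, 100.0))
    elif label == ABNORMAL:
        rr = float(rng.uniform(1.25, 1.8) * rr_typical)
        etco2 = float(rng.choice([rng.uniform(25.0, 34.0), rng.uniform(46.0, 60.0)]))
        spo2 = float(rng.uniform(88.0, 97.0))
        hr = float(rng.uniform(80.0, 130.0))
    else:
        raise ValueError(f"unknown label: {label!r}")
    return VitalSigns(subject_id=f"{label}-vitals-{seed}", rr=rr, etco2=etco2,
                      spo2=spo2, hr=hr, age_years=float(age_years))
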