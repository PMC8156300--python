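"""Respiratory indices from a dual-band recording.

Four quantities describe thoraco-abdominal asynchrony (TAA) and the
compartmental split of tidal breathing:

phase difference (deg)
    Cross-spectral phase between rib-cage and abdomen at the dominant
    breathing frequency, folded to [0, 180].  0 means synchronous
    compartments, 180 paradoxical motion.
%RC
    Rib-cage amplitude as a percentage of the combined rib-cage plus
    abdomen amplitude; about 50% in quiet tidal breathing.
LBI (labored breathing index)
    Ratio of the as-if-in-unison amplitude sum (A_rc + A_abd, the
    maximum compartmental excursion if the compartments moved in perfect
    unison) to the amplitude of the recorded sum signal, whose excursion
    plays the role of tidal volume.  Exactly 1 for in-phase motion and
    grows with asynchrony.
respiratory rate (breaths/min)
    60 times the dominant spectral frequency of the summed signal.

All indices are computed on sliding windows (defaults: 30 s window, 5 s
step — at least five breath cycles per window down to 10 breaths/min,
and ~31 phase samples over a 3-minute recording for the distributional
summary downstream).  Each window is linearly detrended and Hann-tapered
before the FFT.  Amplitudes use the sinusoid-consistent estimator
``sqrt(2) * RMS`` of the detrended window, which is robust to
single-sample spikes; peak-to-peak/2 is available as an alternative.
Every index is a ratio or an angle, hence invariant to rescaling both
channels by any positive constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft, rfftfreq

from .signal_io import BandRecording

logger = logging.getLogger("taarip")

DEFAULT_WINDOW_S = 30.0
DEFAULT_STEP_S = 5.0

#: Plausible breathing band (Hz): 3 to 120 breaths/min.
RESP_BAND_HZ = (0.05, 2.0)

AmplitudeMethod = Literal["rms", "ptp"]


@dataclass
class IndexSeries:
    """Per-window phase/%RC/LBI plus the recording-level breathing rate."""

    window_starts: np.ndarray  # seconds
    phase_deg: np.ndarray      # [0, 180]
    rc_percent: np.ndarray     # [0, 100]
    lbi: np.ndarray            # >= 1 (inf = perfect cancellation)
    rr_bpm: float
    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        n = len(self.window_starts)
        if not (len(self.phase_deg) == len(self.rc_percent) == len(self.lbi) == n):
            raise ValueError("per-window arrays must have equal length")

    @property
    def mean_phase_deg(self) -> float:
        return float(np.mean(self.phase_deg))

    @property
    def mean_rc_percent(self) -> float:
        return float(np.mean(self.rc_percent))

    @property
    def mean_lbi(self) -> float:
        finite = self.lbi[np.isfinite(self.lbi)]
        return float(np.mean(finite)) if finite.size else float("inf")


def window_slices(rec: BandRecording, window_s: float, step_s: float) -> list[tuple[int, int]]:
    """Sliding-window sample index ranges; one full-recording window if too short."""
    if step_s > window_s:
        raise ValueError("step_s must not exceed window_s")
    n_win = int(round(window_s * rec.fs))
    n_step = int(round(step_s * rec.fs))
    if n_win >= rec.n_samples:
        return [(0, rec.n_samples)]
    starts = range(0, rec.n_samples - n_win + 1, n_step)
    return [(s, s + n_win) for s in starts]


def _detrend(x: np.ndarray) -> np.ndarray:
    return sps.detrend(x, type="linear")


def _amplitude(x: np.ndarray, method: AmplitudeMethod = "rms") -> float:
    """Oscillation amplitude of a detrended window."""
    if method == "rms":
        return float(np.sqrt(2.0) * np.sqrt(np.mean(x * x)))
    if method == "ptp":
        return float(np.ptp(x) / 2.0)
    raise ValueError(f"unknown amplitude method: {method!r}")


def _dominant_bin(rc_w: np.ndarray, abd_w: np.ndarray, fs: float):
    """Index of the dominant shared breathing frequency and the tapered FFTs.

    The bin maximizing the product of the two channel power spectra
    within the breathing band is chosen: it favors frequencies with
    energy in *both* compartments when the channels peak at different
    bins.  Returns None if either channel has zero variance.
    """
    if np.ptp(rc_w) == 0 or np.ptp(abd_w) == 0:
        return None
    n = len(rc_w)
    taper = sps.windows.hann(n, sym=False)
    frc = rfft(_detrend(rc_w) * taper)
    fabd = rfft(_detrend(abd_w) * taper)
    freqs = rfftfreq(n, d=1.0 / fs)
    band = (freqs >= RESP_BAND_HZ[0]) & (freqs <= RESP_BAND_HZ[1])
    if not band.any():
        return None
    power_product = (np.abs(frc) ** 2) * (np.abs(fabd) ** 2)
    power_product[~band] = 0.0
    k = int(np.argmax(power_product))
    if power_product[k] == 0.0:
        return None
    return k, frc, fabd, freqs


def estimate_phase(
    rec: BandRecording,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window |cross-spectral phase| between RC and ABD, in degrees.

    For each window: detrend, Hann-taper, FFT both channels, locate the
    dominant breathing bin, and take the cross-spectrum phase there,
    folded into [0, 180] (asynchrony is treated as an unsigned
    magnitude).  Returns ``(window_starts_s, phase_deg)``; windows with a
    zero-variance channel are skipped with a warning.
    """
    slices = window_slices(rec, window_s, step_s)
    starts, phases = [], []
    for i0, i1 in slices:
        res = _dominant_bin(rec.rc[i0:i1], rec.abd[i0:i1], rec.fs)
        if res is None:
            logger.warning("skipping window at %.1fs: zero-variance channel", i0 / rec.fs)
            continue
        k, frc, fabd, _ = res
        cross = frc[k] * np.conj(fabd[k])
        phases.append(abs(np.degrees(np.angle(cross))))
        starts.append(i0 / rec.fs)
    if not phases:
        raise ValueError("no usable windows for phase estimation")
    n_breaths = window_s * _rough_rate_hz(rec)
    if n_breaths < 3:
        logger.warning("window holds only %.1f breath cycles (<3); phase may be noisy", n_breaths)
    return np.asarray(starts), np.asarray(phases)


def _rough_rate_hz(rec: BandRecording) -> float:
    """Coarse dominant breathing frequency for diagnostics; never raises."""
    try:
        return estimate_rr(rec) / 60.0
    except ValueError:
        return 0.25


def compute_rc_percent(
    rec: BandRecording,
    windows: list[tuple[int, int]],
    amplitude_method: AmplitudeMethod = "rms",
) -> np.ndarray:
    """Per-window rib-cage contribution ``100 * A_rc / (A_rc + A_abd)``."""
    if not windows:
        raise ValueError("windows must be nonempty")
    out = []
    for i0, i1 in windows:
        a_rc = _amplitude(_detrend(rec.rc[i0:i1]), amplitude_method)
        a_abd = _amplitude(_detrend(rec.abd[i0:i1]), amplitude_method)
        if a_rc + a_abd == 0:
            logger.warning("skipping window at %.1fs: both channels flat", i0 / rec.fs)
            out.append(np.nan)
            continue
        out.append(100.0 * a_rc / (a_rc + a_abd))
    return np.asarray(out)


def compute_lbi(
    rec: BandRecording,
    windows: list[tuple[int, int]],
    amplitude_method: AmplitudeMethod = "rms",
    cancellation_rtol: float = 1e-9,
) -> np.ndarray:
    """Per-window labored breathing index ``(A_rc + A_abd) / A_sum``.

    ``A_sum`` is the amplitude of the detrended sum signal rc + abd.  By
    the triangle inequality LBI >= 1, with equality for in-phase motion;
    tiny negative excursions below 1 (numerical noise) are clipped to 1.
    Perfect cancellation (A_sum ~ 0) yields an ``inf`` sentinel.
    """
    if not windows:
        raise ValueError("windows must be nonempty")
    out = []
    for i0, i1 in windows:
        a_rc = _amplitude(_detrend(rec.rc[i0:i1]), amplitude_method)
        a_abd = _amplitude(_detrend(rec.abd[i0:i1]), amplitude_method)
        a_sum = _amplitude(_detrend(rec.rc[i0:i1] + rec.abd[i0:i1]), amplitude_method)
        if a_sum <= cancellation_rtol * (a_rc + a_abd):
            logger.warning("window at %.1fs: compartments cancel; LBI -> inf", i0 / rec.fs)
            out.append(np.inf)
            continue
        out.append(max(1.0, (a_rc + a_abd) / a_sum))
    return np.asarray(out)


def estimate_rr(rec: BandRecording, min_duration_s: float = 30.0) -> float:
    """Breathing rate in breaths/min from the summed detrended signal.

    The dominant spectral peak within the breathing band is refined by
    parabolic interpolation on log power across the three bins around the
    maximum, giving sub-bin frequency resolution.
    """
    if rec.duration_s < min_duration_s:
        raise ValueError(f"recording shorter than {min_duration_s:.0f}s; cannot estimate rate")
    x = _detrend(rec.rc + rec.abd)
    if np.ptp(x) == 0:
        raise ValueError("flat summed signal; no respiratory peak")
    n = len(x)
    taper = sps.windows.hann(n, sym=False)
    spec = np.abs(rfft(x * taper)) ** 2
    freqs = rfftfreq(n, d=1.0 / rec.fs)
    band = (freqs >= RESP_BAND_HZ[0]) & (freqs <= RESP_BAND_HZ[1])
    in_band = spec.copy()
    in_band[~band] = 0.0
    k = int(np.argmax(in_band))
    # require the peak to stand clearly above the typical in-band level
    floor = float(np.median(spec[band]))
    if in_band[k] <= 10.0 * max(floor, np.finfo(float).tiny):
        raise ValueError("no respiratory spectral peak above the noise floor")
    f_peak = freqs[k]
    if 0 < k < len(spec) - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        la, lb, lc = np.log(spec[k - 1 : k + 2])
        denom = la - 2 * lb + lc
        if denom < 0:
            delta = 0.5 * (la - lc) / denom
            f_peak = freqs[k] + delta * (freqs[1] - freqs[0])
    return float(60.0 * f_peak)


def compute_indices(
    rec: BandRecording,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    amplitude_method: AmplitudeMethod = "rms",
) -> IndexSeries:
    """All per-window indices plus the recording-level breathing rate."""
    windows = window_slices(rec, window_s, step_s)
    starts, phase = estimate_phase(rec, window_s, step_s)
    rc_pct = compute_rc_percent(rec, windows, amplitude_method)
    lbi = compute_lbi(rec, windows, amplitude_method)
    # align: phase skips zero-variance windows; drop the same windows elsewhere
    all_starts = np.array([i0 / rec.fs for i0, _ in windows])
    keep = np.isin(np.round(all_starts, 9), np.round(starts, 9))
    return IndexSeries(
        window_starts=starts,
        phase_deg=phase,
        rc_percent=rc_pct[keep],
        lbi=lbi[keep],
        rr_bpm=estimate_rr(rec),
        window_s=window_s,
        step_s=step_s,
    )
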