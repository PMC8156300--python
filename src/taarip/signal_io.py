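"""Reading, writing and quality review of dual-band breathing recordings.

A recording holds the rib-cage (RC) and abdominal (ABD) band-excursion
signals of a respiratory-inductance-plethysmography session, sampled
uniformly.  Band excursions are in arbitrary calibrated units: every
downstream index (phase, %RC, LBI) is a ratio or an angle, so no volume
calibration is attempted.

File formats
------------
Recording CSV
    header ``t,rc,abd``; ``t`` in seconds; UTF-8, LF line endings.
Vitals JSON
    ``{"subject_id": str, "rr": num|null, "etco2": num|null,
    "spo2": num|null, "hr": num|null, "age_years": num|null}``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("taarip")

#: Default sampling rate (Hz). At least 10x the highest plausible
#: breathing frequency (~1.2 Hz), so respiratory spectra are well resolved.
DEFAULT_FS = 50.0

#: Maximum tolerated fraction of missing samples; small gaps are treated
#: as sensor dropouts and linearly interpolated.
MAX_NAN_FRACTION = 0.05


class FormatError(ValueError):
    """The file does not follow the documented recording dialect."""


class QualityError(ValueError):
    """The recording content is unusable (e.g. too many missing samples)."""


@dataclass
class BandRecording:
    """Uniformly sampled rib-cage and abdomen excursion signals.

    Attributes
    ----------
    subject_id : str
        Identifier carried through to reports.
    fs : float
        Sampling rate in Hz, > 0.
    t : ndarray
        Sample times in seconds, uniform spacing ``1/fs``.
    rc, abd : ndarray
        Rib-cage and abdomen excursions, arbitrary calibrated units.
    """

    subject_id: str
    fs: float
    t: np.ndarray
    rc: np.ndarray
    abd: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rc = np.asarray(self.rc, dtype=float)
        self.abd = np.asarray(self.abd, dtype=float)
        if not (len(self.t) == len(self.rc) == len(self.abd)):
            raise ValueError("t, rc, abd must have equal length")
        if len(self.t) < 2:
            raise ValueError("a recording needs at least 2 samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.rc).any() or np.isnan(self.abd).any():
            raise ValueError("recording contains NaN after validation")

    @property
    def duration_s(self) -> float:
        """Recording span in seconds, ``(n - 1) / fs``."""
        return (len(self.t) - 1) / self.fs

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class VitalSigns:
    """Per-subject vital-sign summary; any field may be absent (None).

    rr is breaths/min, etco2 is end-tidal CO2 in mmHg, spo2 is blood
    oxygen saturation in percent, hr is beats/min.
    """

    subject_id: str = ""
    rr: Optional[float] = None
    etco2: Optional[float] = None
    spo2: Optional[float] = None
    hr: Optional[float] = None
    age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.spo2 is not None and not 0 <= self.spo2 <= 100:
            raise ValueError("spo2 must lie in [0, 100]")
        for name in ("rr", "etco2", "hr"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class KonnoMeadLoop:
    """Mean-centered (rc, abd) sample pairs for an abd-vs-rc loop plot."""

    rc: np.ndarray
    abd: np.ndarray

    def enclosed_area(self) -> float:
        """Shoelace area of the loop; 0 for in-phase motion, maximal at 90° lag."""
        x, y = self.rc, self.abd
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class QualityFinding:
    """One signal-quality issue; an empty findings list means pass."""

    kind: str  # too-short | flatline | clipping | excessive-nan
    channel: Optional[str] = None
    detail: str = ""

    def __str__(self) -> str:
        chan = f": {self.channel}" if self.channel else ""
        return f"{self.kind}{chan}" + (f" ({self.detail})" if self.detail else "")


def read_recording(
    path,
    fs_override: Optional[float] = None,
    subject_id: Optional[str] = None,
) -> BandRecording:
    """Read a ``t,rc,abd`` CSV into a validated :class:`BandRecording`.

    The time column must be strictly increasing; its median spacing
    defines the sampling rate unless ``fs_override`` is given, and the
    time axis is regularized to exactly uniform spacing.  Up to 5%
    missing samples per channel are linearly interpolated (with a
    warning); more raises :class:`QualityError`.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse recording CSV {path}: {exc}") from exc
    missing = {"t", "rc", "abd"} - set(df.columns)
    if missing:
        raise FormatError(f"recording CSV missing column(s): {sorted(missing)}")
    if len(df) < 2:
        raise FormatError("recording CSV has fewer than 2 rows")

    t = df["t"].to_numpy(dtype=float)
    if np.isnan(t).any() or np.any(np.diff(t) <= 0):
        raise FormatError("time column must be strictly increasing without gaps")

    fs = fs_override if fs_override is not None else 1.0 / float(np.median(np.diff(t)))
    n = len(t)
    t_uniform = t[0] + np.arange(n) / fs

    channels = {}
    for name in ("rc", "abd"):
        x = df[name].to_numpy(dtype=float)
        nan_frac = float(np.isnan(x).mean())
        if nan_frac > MAX_NAN_FRACTION:
            raise QualityError(
                f"channel {name}: {nan_frac:.1%} missing samples exceeds "
                f"{MAX_NAN_FRACTION:.0%} limit"
            )
        if nan_frac > 0:
            logger.warning(
                "channel %s: interpolating %.2f%% missing samples", name, 100 * nan_frac
            )
            good = ~np.isnan(x)
            x = np.interp(np.arange(n), np.flatnonzero(good), x[good])
        channels[name] = x

    sid = subject_id if subject_id is not None else str(path)
    return BandRecording(subject_id=sid, fs=fs, t=t_uniform, rc=channels["rc"], abd=channels["abd"])


def write_recording(rec: BandRecording, path) -> None:
    """Write a recording as a ``t,rc,abd`` CSV; round-trips signal values exactly."""
    df = pd.DataFrame({"t": rec.t, "rc": rec.rc, "abd": rec.abd})
    # repr-precision floats so read_recording reproduces values bit-equal
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_vitals(path) -> VitalSigns:
    """Read a vitals JSON file into a :class:`VitalSigns`."""
    with open(path, "r", encoding="utf-8") as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict):
        raise FormatError("vitals JSON must be an object")
    known = {"subject_id", "rr", "etco2", "spo2", "hr", "age_years"}
    return VitalSigns(**{k: v for k, v in obj.items() if k in known})


def write_vitals(vitals: VitalSigns, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "subject_id": vitals.subject_id,
                "rr": vitals.rr,
                "etco2": vitals.etco2,
                "spo2": vitals.spo2,
                "hr": vitals.hr,
                "age_years": vitals.age_years,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def validate_recording(
    rec: BandRecording,
    min_duration_s: float = 150.0,
    clip_fraction: float = 0.02,
) -> list[QualityFinding]:
    """Screen a recording for quality issues; pure, returns findings.

    Checks: minimum duration, flatline channels, clipping (a large share
    of samples pinned at a channel's extremes).  Thresholds are this
    package's operationalization of "good signal quality" review.
    """
    findings: list[QualityFinding] = []
    if rec.duration_s < min_duration_s:
        findings.append(
            QualityFinding("too-short", detail=f"{rec.duration_s:.1f}s < {min_duration_s:.0f}s")
        )
    for name in ("rc", "abd"):
        x = getattr(rec, name)
        if np.ptp(x) == 0:
            findings.append(QualityFinding("flatline", channel=name))
            continue
        lo, hi = x.min(), x.max()
        pinned = float(np.mean((x == lo) | (x == hi)))
        if pinned > clip_fraction:
            findings.append(
                QualityFinding("clipping", channel=name, detail=f"{pinned:.1%} samples at rails")
            )
    return findings


def konno_mead(
    rec: BandRecording,
    segment: Optional[tuple[float, float]] = None,
) -> KonnoMeadLoop:
    """Extract mean-centered (rc, abd) pairs for a Konno–Mead loop.

    The loop of abdominal vs. rib-cage excursion collapses to a line for
    synchronous breathing and opens with asynchrony; its enclosed area on
    sinusoids is ``pi * A_rc * A_abd * |sin(phase)|``.
    """
    if segment is None:
        i0, i1 = 0, rec.n_samples
    else:
        t0, t1 = segment
        i0 = int(np.searchsorted(rec.t, t0, side="left"))
        i1 = int(np.searchsorted(rec.t, t1, side="right"))
    if i1 - i0 < 2:
        raise ValueError("empty or degenerate Konno-Mead segment")
    rc = rec.rc[i0:i1]
    abd = rec.abd[i0:i1]
    return KonnoMeadLoop(rc=rc - rc.mean(), abd=abd - abd.mean())
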