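"""Per-subject abnormality flagging and assessment-report assembly.

Each respiratory index is flagged normal / abnormal / unavailable
against healthy references:

* RR, %RC, LBI — deviation rule: abnormal when the value lies more than
  20% (configurable) away from the age-matched healthy mean; boundary
  values count as normal.
* mean phase — one-sided deviation rule: abnormal only when the value
  exceeds the healthy mean by more than the deviation fraction (a large
  phase lag is pathological; a small one is not).  Configurable to
  two-sided.
* ETCO2 — healthy range 35–45 mmHg inclusive.
* SpO2 — normal strictly above 95%.

The shipped healthy reference table is an illustrative, editable JSON of
synthetic placeholder values by age band; real deployments supply their
own.  Clinical metadata (diagnosis, surgery history) is pass-through
only and never computed on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .indices import IndexSeries
from .signal_io import VitalSigns

NORMAL_FLAG = "normal"
ABNORMAL_FLAG = "abnormal"
UNAVAILABLE = "unavailable"

Flag = str  # one of the three states above

FLAG_INDEX_NAMES = ("rr", "etco2", "spo2", "rc_percent", "lbi", "phase", "icp_classifier")


@dataclass
class AgeBandReference:
    """Healthy index means for one age band [age_lo, age_hi)."""

    age_lo: float
    age_hi: float
    rr_mean: float
    rc_percent_mean: float
    lbi_mean: float
    phase_mean: float


@dataclass
class ReferenceRanges:
    """Healthy reference values used by the flag rules."""

    age_bands: list[AgeBandReference]
    etco2_range: tuple[float, float] = (35.0, 45.0)
    spo2_min: float = 95.0
    deviation_fraction: float = 0.20

    def __post_init__(self) -> None:
        lo, hi = self.etco2_range
        if lo > hi:
            raise ValueError("etco2_range is not well-ordered")
        if not 0 < self.deviation_fraction < 1:
            raise ValueError("deviation_fraction must lie in (0, 1)")

    def band_for_age(self, age_years: Optional[float]) -> Optional[AgeBandReference]:
        if age_years is None:
            return None
        for band in self.age_bands:
            if band.age_lo <= age_years < band.age_hi:
                return band
        return None

    @classmethod
    def from_json(cls, path) -> "ReferenceRanges":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls._from_obj(obj)

    @classmethod
    def _from_obj(cls, obj: dict) -> "ReferenceRanges":
        bands = [AgeBandReference(**b) for b in obj["age_bands"]]
        return cls(
            age_bands=bands,
            etco2_range=tuple(obj.get("etco2_range", (35.0, 45.0))),
            spo2_min=float(obj.get("spo2_min", 95.0)),
            deviation_fraction=float(obj.get("deviation_fraction", 0.20)),
        )

    @classmethod
    def default(cls) -> "ReferenceRanges":
        """The shipped illustrative reference table."""
        text = resources.files("taarip").joinpath("data/reference_ranges.json").read_text()
        return cls._from_obj(json.loads(text))

    def to_json(self, path) -> None:
        obj = {
            "deviation_fraction": self.deviation_fraction,
            "etco2_range": list(self.etco2_range),
            "spo2_min": self.spo2_min,
            "age_bands": [vars(b) for b in self.age_bands],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")


@dataclass
class AssessmentReport:
    """Per-subject flags per index plus the classifier verdict."""

    subject_id: str
    age_years: Optional[float]
    flags: dict[str, Flag]
    classifier_probability: Optional[float] = None
    clinical_diagnosis: str = ""
    surgery: str = ""

    def __post_init__(self) -> None:
        bad = {v for v in self.flags.values()} - {NORMAL_FLAG, ABNORMAL_FLAG, UNAVAILABLE}
        if bad:
            raise ValueError(f"invalid flag state(s): {sorted(bad)}")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "age_years": self.age_years,
            "flags": dict(self.flags),
            "classifier_probability": self.classifier_probability,
            "clinical_diagnosis": self.clinical_diagnosis,
            "surgery": self.surgery,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "AssessmentReport":
        return cls(
            subject_id=obj["subject_id"],
            age_years=obj["age_years"],
            flags=dict(obj["flags"]),
            classifier_probability=obj.get("classifier_probability"),
            clinical_diagnosis=obj.get("clinical_diagnosis", ""),
            surgery=obj.get("surgery", ""),
        )


def flag_by_deviation(
    value: Optional[float],
    healthy_mean: float,
    deviation_fraction: float = 0.20,
    sided: Literal["two", "above"] = "two",
) -> Flag:
    """Deviation-from-healthy-mean rule; boundary values are normal.

    Two-sided: abnormal iff |value - mean| > fraction * mean.  One-sided
    'above': abnormal only when value exceeds mean by more than the
    fraction (used for phase, where only large lags are pathological).
    """
    if healthy_mean <= 0:
        raise ValueError("healthy_mean must be positive")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNAVAILABLE
    dev = value - healthy_mean
    if sided == "above":
        exceeded = dev > deviation_fraction * healthy_mean
    elif sided == "two":
        exceeded = abs(dev) > deviation_fraction * healthy_mean
    else:
        raise ValueError(f"unknown sidedness: {sided!r}")
    return ABNORMAL_FLAG if exceeded else NORMAL_FLAG


def flag_by_range(value: Optional[float], lo: float, hi: float) -> Flag:
    """Inclusive-range rule (used for ETCO2, healthy 35–45 mmHg)."""
    if lo > hi:
        raise ValueError("range is not well-ordered")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNAVAILABLE
    return NORMAL_FLAG if lo <= value <= hi else ABNORMAL_FLAG


def flag_spo2(value: Optional[float], min_pct: float = 95.0) -> Flag:
    """Oxygen-saturation rule: normal strictly above the cutoff."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNAVAILABLE
    return NORMAL_FLAG if value > min_pct else ABNORMAL_FLAG


def build_report(
    indices: Optional[IndexSeries],
    vitals: Optional[VitalSigns],
    verdict: Optional[tuple[float, str]],
    refs: ReferenceRanges,
    subject_id: str = "",
    age_years: Optional[float] = None,
    clinical_diagnosis: str = "",
    surgery: str = "",
    phase_sided: Literal["two", "above"] = "above",
) -> AssessmentReport:
    """Assemble the per-subject flag report.

    Mean index values and vitals are flagged against the age-matched
    references; anything missing (vitals absent, age outside the
    reference table) degrades to 'unavailable' rather than failing.
    ``verdict`` is the (probability, label) pair from the classifier.
    """
    if age_years is None and vitals is not None:
        age_years = vitals.age_years
    band = refs.band_for_age(age_years)
    frac = refs.deviation_fraction
    flags: dict[str, Flag] = {}

    rr_value = vitals.rr if vitals is not None else None
    if rr_value is None and indices is not None:
        rr_value = indices.rr_bpm  # fall back to the signal-derived rate
    flags["rr"] = (
        flag_by_deviation(rr_value, band.rr_mean, frac) if band else UNAVAILABLE
    )
    flags["etco2"] = flag_by_range(
        vitals.etco2 if vitals else None, *refs.etco2_range
    )
    flags["spo2"] = flag_spo2(vitals.spo2 if vitals else None, refs.spo2_min)

    if indices is not None and band is not None:
        flags["rc_percent"] = flag_by_deviation(indices.mean_rc_percent, band.rc_percent_mean, frac)
        mean_lbi = indices.mean_lbi
        flags["lbi"] = (
            ABNORMAL_FLAG if np.isinf(mean_lbi)
            else flag_by_deviation(mean_lbi, band.lbi_mean, frac)
        )
        flags["phase"] = flag_by_deviation(
            indices.mean_phase_deg, band.phase_mean, frac, sided=phase_sided
        )
    else:
        flags["rc_percent"] = flags["lbi"] = flags["phase"] = UNAVAILABLE

    prob: Optional[float] = None
    if verdict is not None:
        prob, label = verdict
        flags["icp_classifier"] = ABNORMAL_FLAG if label == "abnormal" else NORMAL_FLAG
    else:
        flags["icp_classifier"] = UNAVAILABLE

    return AssessmentReport(
        subject_id=subject_id,
        age_years=age_years,
        flags=flags,
        classifier_probability=prob,
        clinical_diagnosis=clinical_diagnosis,
        surgery=surgery,
    )


def reports_to_frame(reports: list[AssessmentReport]) -> pd.DataFrame:
    """Tabulate reports, one row per subject, one column per flag."""
    rows = []
    for r in reports:
        row = {"subject_id": r.subject_id, "age_years": r.age_years}
        row.update({name: r.flags.get(name, UNAVAILABLE) for name in FLAG_INDEX_NAMES})
        row["classifier_probability"] = r.classifier_probability
        row["surgery"] = r.surgery
        row["clinical_diagnosis"] = r.clinical_diagnosis
        rows.append(row)
    return pd.DataFrame(rows)


def save_reports(reports: list[AssessmentReport], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
        fh.write("\n")


def load_reports(path) -> list[AssessmentReport]:
    with open(path, "r", encoding="utf-8") as fh:
        return [AssessmentReport.from_dict(obj) for obj in json.load(fh)]
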