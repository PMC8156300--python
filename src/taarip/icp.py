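"""Inverse cumulative percentage (ICP) summary of a phase series.

The ICP is the empirical survival function of the windowed phase series
expressed in percent: for each angle on a 0–180 degree integer grid it
gives the percentage of windows whose phase is at or above that angle.
It always starts at 100% and is non-increasing; a synchronous breather's
curve drops immediately, while sustained asynchrony keeps it high out to
large angles.  Being a distributional summary it is robust to outliers
and invariant to the time ordering of the windows.

Quantile markers (median, 25th, 75th percentile) are read off the curve:
the marker for percentage q is the largest grid angle whose ICP strictly
exceeds q.  On grid-valued data this matches the type-1 empirical
quantile (``numpy.quantile(..., method='inverted_cdf')``), and it is
deterministic on the step functions the ICP produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .synthetic import NORMAL, ABNORMAL

#: Integer-degree grid covering the folded phase range.
GRID_DEG = np.arange(0, 181)

#: Default feature grid: every 5 degrees, 37 predictors.
DEFAULT_FEATURE_GRID_DEG = np.arange(0, 181, 5)


@dataclass
class ICPCurve:
    """ICP values on the integer-degree grid with quantile markers."""

    grid_deg: np.ndarray
    icp_pct: np.ndarray
    median_deg: float
    q25_deg: float
    q75_deg: float

    def __post_init__(self) -> None:
        if len(self.grid_deg) != len(self.icp_pct):
            raise ValueError("grid and ICP arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta_deg": self.grid_deg, "icp_pct": self.icp_pct})


@dataclass
class ReferenceEnvelope:
    """Pointwise normal/abnormal ICP bands from a labelled cohort."""

    grid_deg: np.ndarray
    normal_lo: np.ndarray
    normal_hi: np.ndarray
    abnormal_lo: np.ndarray
    abnormal_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_deg": self.grid_deg,
                "normal_lo": self.normal_lo,
                "normal_hi": self.normal_hi,
                "abnormal_lo": self.abnormal_lo,
                "abnormal_hi": self.abnormal_hi,
            }
        )


def _marker(grid: np.ndarray, icp: np.ndarray, threshold_pct: float) -> float:
    """Largest grid angle whose ICP strictly exceeds the threshold."""
    above = icp > threshold_pct
    if not above.any():
        return float(grid[0])
    return float(grid[np.flatnonzero(above)[-1]])


def compute_icp(phase_deg: Sequence[float]) -> ICPCurve:
    """Empirical survival curve of a phase series on the integer grid.

    ``icp_pct[theta] = 100 * #{phase >= theta} / n`` with median/q25/q75
    markers under the strict-exceedance tie rule documented above.
    """
    phase = np.asarray(phase_deg, dtype=float)
    if phase.size == 0:
        raise ValueError("phase series is empty")
    # counts of phases >= theta via a sorted search
    srt = np.sort(phase)
    n_ge = phase.size - np.searchsorted(srt, GRID_DEG, side="left")
    icp = 100.0 * n_ge / phase.size
    return ICPCurve(
        grid_deg=GRID_DEG.copy(),
        icp_pct=icp,
        median_deg=_marker(GRID_DEG, icp, 50.0),
        q25_deg=_marker(GRID_DEG, icp, 75.0),
        q75_deg=_marker(GRID_DEG, icp, 25.0),
    )


def build_envelopes(
    curves: Sequence[ICPCurve],
    labels: Sequence[str],
    band: Literal["minmax", "percentile"] = "minmax",
    percentile_span: tuple[float, float] = (5.0, 95.0),
) -> ReferenceEnvelope:
    """Pointwise per-class ICP bands from a labelled cohort of curves.

    With ``band='minmax'`` (default) the band is the pointwise min and
    max over each class; ``'percentile'`` uses the given percentile span
    instead, which is less sensitive to a single extreme subject.
    """
    if len(curves) != len(labels):
        raise ValueError("curves and labels must have equal length")
    stacked = {
        lab: np.array([c.icp_pct for c, l in zip(curves, labels) if l == lab])
        for lab in (NORMAL, ABNORMAL)
    }
    for lab, arr in stacked.items():
        if arr.size == 0:
            raise ValueError(f"no curves labelled {lab!r}")
    if band == "minmax":
        lo_hi = {lab: (arr.min(axis=0), arr.max(axis=0)) for lab, arr in stacked.items()}
    elif band == "percentile":
        p_lo, p_hi = percentile_span
        lo_hi = {
            lab: (np.percentile(arr, p_lo, axis=0), np.percentile(arr, p_hi, axis=0))
            for lab, arr in stacked.items()
        }
    else:
        raise ValueError(f"unknown band type: {band!r}")
    return ReferenceEnvelope(
        grid_deg=GRID_DEG.copy(),
        normal_lo=lo_hi[NORMAL][0],
        normal_hi=lo_hi[NORMAL][1],
        abnormal_lo=lo_hi[ABNORMAL][0],
        abnormal_hi=lo_hi[ABNORMAL][1],
    )


def icp_features(
    curve: ICPCurve,
    feature_grid_deg: np.ndarray | Sequence[int] = DEFAULT_FEATURE_GRID_DEG,
) -> np.ndarray:
    """Fixed-order predictor vector: ICP sampled at the feature grid.

    The default 5-degree grid gives 37 predictors — deliberately more
    than the typical training-cohort size, which is what motivates the
    penalized fit downstream.
    """
    grid = np.asarray(feature_grid_deg)
    if grid.min() < 0 or grid.max() > 180:
        raise ValueError("feature grid must lie within [0, 180] degrees")
    idx = np.searchsorted(curve.grid_deg, grid)
    if not np.array_equal(curve.grid_deg[idx], grid):
        raise ValueError("feature grid angles must be on the curve grid")
    return curve.icp_pct[idx].astype(float)


def icp_plot_data(curve: ICPCurve, envelope: ReferenceEnvelope | None = None) -> pd.DataFrame:
    """Join curve, markers and envelope into one plot-ready table."""
    df = curve.to_frame()
    df["is_median"] = df["theta_deg"] == curve.median_deg
    df["is_q25"] = df["theta_deg"] == curve.q25_deg
    df["is_q75"] = df["theta_deg"] == curve.q75_deg
    if envelope is not None:
        df = df.merge(envelope.to_frame(), on="theta_deg", how="left")
    return df
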