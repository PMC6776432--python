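"""Log-linear standard curves, master curves and copy-number interpolation.

A qPCR standard curve is the ordinary least-squares fit of Ct against
log10(input copies).  Its slope measures amplification efficiency
(E = 10^(-1/slope) - 1; slope -3.3219 is perfect per-cycle doubling) and
its intercept is the expected Ct of a single copy.  A *master curve* is
the same fit pooled over the QC-passing points of many plates/instruments
and is the curve unknowns are interpolated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError

__all__ = [
    "StandardCurveFit",
    "MasterCurve",
    "ReportableRange",
    "fit_standard_curve",
    "build_master_curve",
    "predict_ct",
    "interpolate_copies",
    "reportable_range",
    "curve_table",
]


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS fit of Ct on log10(copies) for one group of points."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int
    group_id: str

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("a curve fit needs at least 2 points")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency


@dataclass(frozen=True)
class MasterCurve:
    """Pooled master fit plus the per-plate member fits it aggregates."""

    master: StandardCurveFit
    members: tuple[StandardCurveFit, ...]


def _efficiency(slope: float) -> float:
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    points: Iterable[tuple[float, float]], group_id: str = "curve"
) -> StandardCurveFit:
    """Fit Ct = intercept + slope * log10(copies) by OLS.

    ``points`` are (copies, ct) pairs; at least two distinct copy levels
    are required.  R² is the squared Pearson correlation of observed and
    fitted Ct (with two points or perfectly collinear input it is 1).
    """
    pts = list(points)
    if len(pts) < 2:
        raise DegenerateFitError("need at least 2 points to fit a standard curve")
    copies = np.array([c for c, _ in pts], dtype=float)
    ct = np.array([t for _, t in pts], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("copy inputs must be positive")
    x = np.log10(copies)
    if np.allclose(x, x[0]):
        raise DegenerateFitError("all points at a single copy level")
    res = stats.linregress(x, ct)
    if res.slope == 0:
        raise DegenerateFitError("fitted slope is zero")
    # rvalue is nan when ct is constant; the line still fits exactly
    r2 = 1.0 if math.isnan(res.rvalue) else float(res.rvalue**2)
    return StandardCurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        efficiency=_efficiency(float(res.slope)),
        n_points=len(pts),
        group_id=group_id,
    )


def build_master_curve(
    points_by_plate: dict[str, Sequence[tuple[float, float]]],
    group_id: str = "master",
) -> MasterCurve:
    """Pool QC-passing points from several plates into one master fit.

    Aggregation pools every point into a single OLS (weighting plates by
    how many passing points they contribute) rather than averaging
    per-plate coefficients; the per-plate member fits are returned
    alongside so either convention can be audited.
    """
    if not points_by_plate:
        raise DegenerateFitError("no plates supplied")
    members = tuple(
        fit_standard_curve(pts, group_id=plate) for plate, pts in sorted(points_by_plate.items())
    )
    pooled = [pt for _, pts in sorted(points_by_plate.items()) for pt in pts]
    master = fit_standard_curve(pooled, group_id=group_id)
    return MasterCurve(master=master, members=members)


def predict_ct(copies: float, fit: StandardCurveFit) -> float:
    """Expected Ct of a given copy input under the fitted curve."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    return fit.intercept + fit.slope * math.log10(copies)


def interpolate_copies(ct: float, fit: StandardCurveFit) -> float:
    """Invert the curve: copies = 10^((ct - intercept) / slope)."""
    if fit.slope == 0:
        raise DegenerateFitError("cannot interpolate against a zero-slope curve")
    return 10.0 ** ((ct - fit.intercept) / fit.slope)


@dataclass(frozen=True)
class ReportableRange:
    """Detection-based reportable range over the dilution levels."""

    min_copies: float | None
    max_copies: float | None
    detected: tuple[tuple[str, float, bool], ...]  # (level name, copies, in range)

    @property
    def is_empty(self) -> bool:
        return self.min_copies is None


def reportable_range(
    levels: Iterable[tuple[str, float, int]],
) -> ReportableRange:
    """Reportable range from per-level detection results.

    ``levels`` are (name, nominal copies, n wells with a QC-passing Ct).
    A level is in range when at least one replicate amplified; the range
    endpoints are the min/max copies among in-range levels.  No detected
    level yields an empty range, not an error.
    """
    flags = tuple((name, float(copies), n_detected >= 1) for name, copies, n_detected in levels)
    in_range = [copies for _, copies, ok in flags if ok]
    if not in_range:
        return ReportableRange(min_copies=None, max_copies=None, detected=flags)
    return ReportableRange(min_copies=min(in_range), max_copies=max(in_range), detected=flags)


def curve_table(fits: Iterable[StandardCurveFit]):
    """Tabulate fits in the conventional regression-summary layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "group_id": f.group_id,
                "y_intercept": round(f.intercept, 4),
                "slope": round(f.slope, 4),
                "efficiency": round(f.efficiency, 4),
                "r_squared": round(f.r_squared, 4),
                "n_points": f.n_points,
            }
            for f in fits
        ]
    )
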