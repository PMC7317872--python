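"""Analytical size-exclusion-chromatography calibration.

The partition coefficient Kav = (Ve - V0)/(Vc - V0) of globular standards is
linear in log10(MW); the fitted line converts elution volumes of unknowns to
apparent molecular weights.  A literal linear-in-MW variant is provided for
comparison but the semi-log form is the default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .exceptions import FitFailureError, InvalidParameterError


@dataclass(frozen=True)
class ColumnGeometry:
    """Void volume V0 and total column volume Vc_col, both mL."""

    V0: float
    Vc_col: float

    def __post_init__(self):
        if not 0 < self.V0 < self.Vc_col:
            raise InvalidParameterError("need 0 < V0 < Vc_col")


@dataclass
class CalibrationCurve:
    slope: float        # d Kav / d log10(MW); negative
    intercept: float
    standards: list     # list of (MW_da, Ve_mL)
    r_squared: float
    log_mw: bool = True  # semi-log (standard) vs literal linear-in-MW

    def summary(self) -> str:
        form = "Kav vs log10(MW)" if self.log_mw else "Kav vs MW"
        return (f"SEC calibration ({form}, {len(self.standards)} standards)\n"
                f"  slope = {self.slope:.5g}, intercept = {self.intercept:.5g},"
                f" R^2 = {self.r_squared:.5f}\n")


def kav(Ve: float, geom: ColumnGeometry) -> float:
    """Partition coefficient Kav = (Ve - V0)/(Vc - V0).

    Values outside [0, 1] are returned as-is (flagged downstream)."""
    return (Ve - geom.V0) / (geom.Vc_col - geom.V0)


def fit_calibration(standards, geom: ColumnGeometry,
                    log_mw: bool = True) -> CalibrationCurve:
    """Least-squares calibration line from >= 3 (MW, Ve) standards.

    A non-negative slope (larger proteins eluting later) is a calibration
    -order error."""
    standards = [(float(mw), float(ve)) for mw, ve in standards]
    if len(standards) < 3:
        raise InvalidParameterError("need at least 3 standards")
    mw = np.array([s[0] for s in standards])
    ve = np.array([s[1] for s in standards])
    x = np.log10(mw) if log_mw else mw
    y = np.array([kav(v, geom) for v in ve])
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise FitFailureError("positive calibration slope: standards are out "
                              "of elution order")
    yhat = slope * x + intercept
    ss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - yhat) ** 2) / ss if ss > 0 else 1.0
    return CalibrationCurve(float(slope), float(intercept), standards,
                            float(r2), log_mw=log_mw)


def apparent_mw(Ve: float, cal: CalibrationCurve, geom: ColumnGeometry):
    """Apparent MW (Da) of a species eluting at Ve, with extrapolation flag.

    Returns ``(mw_da, extrapolated)``: the flag is True when the Kav falls
    outside the calibrated range."""
    k = kav(Ve, geom)
    x = (k - cal.intercept) / cal.slope
    mw = 10.0**x if cal.log_mw else x
    if cal.standards:
        kavs = [kav(v, geom) for _, v in cal.standards]
        extrapolated = not (min(kavs) <= k <= max(kavs))
    else:
        extrapolated = not (0.0 <= k <= 1.0)
    return float(mw), extrapolated


def elution_volume(mw_da: float, cal: CalibrationCurve,
                   geom: ColumnGeometry) -> float:
    """Inverse of :func:`apparent_mw` on the calibration line."""
    x = np.log10(mw_da) if cal.log_mw else mw_da
    k = cal.slope * x + cal.intercept
    return geom.V0 + k * (geom.Vc_col - geom.V0)


def read_standards_csv(path):
    """Standards CSV with columns name, mw_da, ve_ml."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((float(row["mw_da"]), float(row["ve_ml"])))
    return out
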