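"""Bioanalytical QC: linear calibration on area ratios, bias checks, LOQ.

LC-MS quantification reports an *area ratio* (analyte peak area over labeled
internal-standard peak area) which is linear in concentration across each
analyte's validated range. This module fits that line, back-calculates
concentrations, flags samples outside the linear range (below -> BLQ, above
-> dilute and re-measure), and applies the standard +/-10% bias acceptance
to QC samples. The per-analyte limit of quantification consumed by the
permeability stage is the low end of the linear range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import ValidationError

#: Validated linear ranges (ug/mL) per analyte; the low end doubles as LOQ.
LINEAR_RANGES_UG_ML = {
    "atenolol": (0.5, 30.0),
    "metoprolol": (0.2, 40.0),
    "propranolol": (1.0, 300.0),
}

R2_ACCEPTANCE = 0.99
QC_BIAS_LIMIT_PERCENT = 10.0
MIN_CALIBRATION_LEVELS = 5


def loq_ug_ml(analyte: str) -> float:
    """Limit of quantification = low end of the analyte's linear range."""
    try:
        return LINEAR_RANGES_UG_ML[analyte.lower()][0]
    except KeyError:
        raise ValidationError(f"no linear range on record for {analyte!r}") from None


@dataclass
class CalibrationCurve:
    """Least-squares calibration of area ratio against nominal concentration."""

    analyte: str
    buffer_ph: float
    levels: List[Tuple[float, float]]      # (nominal concentration, area ratio)
    slope: float
    intercept: float
    r_squared: float
    linear_range: Tuple[float, float]
    passed: bool                           # r_squared >= acceptance floor
    weighting: Optional[str] = None


def fit_calibration(levels: Sequence[Tuple[float, float]], analyte: str = "",
                    buffer_ph: float = 7.4,
                    linear_range: Optional[Tuple[float, float]] = None,
                    weighting: Optional[str] = None,
                    r2_min: float = R2_ACCEPTANCE) -> CalibrationCurve:
    """Fit area ratio on nominal concentration by (optionally 1/x-weighted) OLS.

    Requires at least five distinct nominal levels. The curve is flagged
    failing when R^2 falls below the acceptance floor (default 0.99); it is
    still returned so the failure can be reported.
    """
    levels = [(float(x), float(y)) for x, y in levels]
    x = np.array([lv[0] for lv in levels])
    y = np.array([lv[1] for lv in levels])
    if len(set(x.tolist())) < MIN_CALIBRATION_LEVELS:
        raise ValidationError(
            f"calibration needs >= {MIN_CALIBRATION_LEVELS} distinct levels, "
            f"got {len(set(x.tolist()))}")
    if np.all(x == x[0]):
        raise ValidationError("zero variance in nominal concentrations")
    if weighting is None:
        w = np.ones_like(x)
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise ValidationError("1/x weighting requires positive nominals")
        w = 1.0 / x
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")

    wsum = w.sum()
    xm = (w * x).sum() / wsum
    ym = (w * y).sum() / wsum
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm

    resid = y - (intercept + slope * x)
    ss_res = float((w * resid ** 2).sum())
    ss_tot = float((w * (y - ym) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    rng = linear_range or (float(x.min()), float(x.max()))
    return CalibrationCurve(analyte=analyte, buffer_ph=buffer_ph, levels=levels,
                            slope=float(slope), intercept=float(intercept),
                            r_squared=r2, linear_range=rng,
                            passed=r2 >= r2_min, weighting=weighting)


def quantify(area_ratio: float, curve: CalibrationCurve) -> Tuple[float, str]:
    """Back-calculate a concentration from an area ratio.

    Returns ``(concentration, flag)`` with flag ``"ok"``, ``"blq"`` (below
    the linear range) or ``"over_range"`` (above it; dilute and re-measure).
    """
    if curve.slope == 0:
        raise ValidationError("calibration slope is zero; cannot invert")
    conc = (area_ratio - curve.intercept) / curve.slope
    low, high = curve.linear_range
    if conc < low:
        return conc, "blq"
    if conc > high:
        return conc, "over_range"
    return conc, "ok"


@dataclass
class QCResult:
    """Accuracy of one QC sample against its nominal concentration."""

    nominal: float
    measured: float
    bias_percent: float
    passed: bool


def qc_bias(nominal: float, measured: float,
            limit_percent: float = QC_BIAS_LIMIT_PERCENT) -> QCResult:
    """Bias% = 100*(measured - nominal)/nominal with the |bias| <= 10% rule."""
    if not (math.isfinite(nominal) and nominal > 0):
        raise ValidationError(f"nominal must be > 0, got {nominal!r}")
    bias = 100.0 * (measured - nominal) / nominal
    return QCResult(nominal=nominal, measured=measured, bias_percent=bias,
                    passed=abs(bias) <= limit_percent)
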