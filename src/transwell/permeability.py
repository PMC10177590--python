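"""Apparent-permeability estimation with serial-sampling and recovery corrections.

Pipeline for one well::

    receiver series --> cumulative correction --> transfer-slope OLS
        --> Papp_uncorrected = V_R / (A * C_0) * dC/dt
        --> recovery = (donor_end * V_D + corrected_receiver_end * V_R)
                        / (donor_start * V_D)
        --> Papp = Papp_uncorrected / recovery

The cumulative correction restores the receiver concentration that would
have been observed had no aliquots been withdrawn: with sampling volume
``V_s`` replaced by blank buffer in a receiver of volume ``V_R``,

    corrected(t_k) = measured(t_k) + (V_s / V_R) * sum_{j<k} measured(t_j)

which makes ``corrected * V_R`` exactly the cumulative transported mass.
Below-LOQ points contribute nothing to the running sum and stay masked.

Two slope conventions are provided: ``full_range`` (one least-squares line
from the first quantifiable point to the end) and ``max_window`` (the
contiguous window of at least ``min_points`` points whose OLS slope is
maximal -- the "maximum slope" reading, which is less sensitive to donor
depletion flattening the late curve).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .model import (
    ConditionSummary,
    Direction,
    PappResult,
    PappStatus,
    TranswellGeometry,
    ValidationError,
    WellTimeSeries,
)

logger = logging.getLogger(__name__)

SECONDS_PER_MINUTE = 60.0


class SlopeMode(str, enum.Enum):
    FULL_RANGE = "full_range"
    MAX_WINDOW = "max_window"


@dataclass
class CumulativeSeries:
    """Receiver concentrations adjusted for drug removed in prior aliquots."""

    times: np.ndarray
    measured: np.ndarray          # NaN at censored points
    corrected: np.ndarray         # NaN at censored points
    quantifiable: np.ndarray      # boolean mask


@dataclass
class SlopeFit:
    """Least-squares transfer-rate fit over a window of cumulative points."""

    slope: float                  # concentration / min
    intercept: float
    r_squared: float
    window: Tuple[int, int]       # (first, last) index into the series, inclusive
    mode: SlopeMode
    n_points: int


@dataclass
class EffluxAssessment:
    """Directional permeability ratio and the conventional >2 efflux call."""

    papp_ab: float
    papp_ba: float
    ratio: float
    active_efflux_flag: bool


@dataclass(frozen=True)
class PappConfig:
    """Tunable knobs of the per-well estimation pipeline."""

    mode: SlopeMode = SlopeMode.FULL_RANGE
    min_points: int = 3
    recovery_upper_bound: float = 1.2
    efflux_threshold: float = 2.0


def correct_cumulative(series: WellTimeSeries,
                       geometry: Optional[TranswellGeometry] = None) -> CumulativeSeries:
    """Adjust each receiver concentration for mass removed in prior aliquots."""
    geometry = geometry or series.design.geometry
    if not geometry.replacement:
        raise ValidationError(
            "cumulative correction assumes aliquots are replaced with blank buffer")
    v_r = geometry.receiver_volume_ml(series.design.direction)
    v_s = geometry.sample_volume_ml
    if v_s >= v_r:
        raise ValidationError("sample volume must be smaller than receiver volume")

    times = np.array([p.time_min for p in series.receiver_measurements], dtype=float)
    measured = np.array([float("nan") if p.below_loq else p.concentration
                         for p in series.receiver_measurements], dtype=float)
    quantifiable = ~np.isnan(measured)

    corrected = np.full_like(measured, float("nan"))
    running = 0.0  # sum of prior measured concentrations
    for k in range(len(measured)):
        if quantifiable[k]:
            corrected[k] = measured[k] + (v_s / v_r) * running
            running += measured[k]
        # censored points contribute 0 to the running sum and stay masked
    return CumulativeSeries(times=times, measured=measured,
                            corrected=corrected, quantifiable=quantifiable)


def _ols(t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Plain least squares returning (slope, intercept, r_squared).

    A perfectly flat series has zero residuals and is reported with
    r_squared = 1 (the line explains everything there is to explain).
    """
    t_mean = t.mean()
    y_mean = y.mean()
    sxx = float(((t - t_mean) ** 2).sum())
    if sxx == 0:
        raise ValidationError("cannot fit a slope to coincident time points")
    sxy = float(((t - t_mean) * (y - y_mean)).sum())
    slope = sxy / sxx
    intercept = y_mean - slope * t_mean
    ss_tot = float(((y - y_mean) ** 2).sum())
    ss_res = float(((y - (intercept + slope * t)) ** 2).sum())
    if ss_tot == 0:
        r2 = 1.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return slope, intercept, r2


def fit_transfer_slope(cumulative: CumulativeSeries,
                       mode: Union[SlopeMode, str] = SlopeMode.FULL_RANGE,
                       min_points: int = 3) -> Optional[SlopeFit]:
    """Estimate the transfer rate dC/dt from the corrected cumulative series.

    Returns ``None`` when fewer than ``min_points`` quantifiable points are
    available -- the below-LOQ signal consumed by :func:`estimate_papp`,
    never an exception.
    """
    mode = SlopeMode(mode)
    idx = np.flatnonzero(cumulative.quantifiable)
    if len(idx) < min_points:
        return None
    t = cumulative.times[idx]
    y = cumulative.corrected[idx]

    if mode is SlopeMode.FULL_RANGE:
        slope, intercept, r2 = _ols(t, y)
        return SlopeFit(slope=slope, intercept=intercept, r_squared=r2,
                        window=(int(idx[0]), int(idx[-1])), mode=mode,
                        n_points=len(idx))

    best: Optional[SlopeFit] = None
    # contiguous windows over the quantifiable points, earliest wins ties
    for start in range(0, len(idx) - min_points + 1):
        for stop in range(start + min_points, len(idx) + 1):
            slope, intercept, r2 = _ols(t[start:stop], y[start:stop])
            if best is None or slope > best.slope + 1e-15 * abs(best.slope):
                best = SlopeFit(slope=slope, intercept=intercept, r_squared=r2,
                                window=(int(idx[start]), int(idx[stop - 1])),
                                mode=mode, n_points=stop - start)
    return best


def papp_uncorrected(slope_conc_per_min: float, c0: float,
                     geometry: TranswellGeometry,
                     direction: Direction) -> float:
    """Uncorrected apparent permeability in cm/s.

    ``(V_R / (A * C_0)) * dC/dt`` with the slope converted from per-minute to
    per-second; ``V_R`` is the receiver volume for the stated direction.
    ``C_0`` and the slope must share the same concentration unit.
    """
    if c0 <= 0 or not math.isfinite(c0):
        raise ValidationError(f"C_0 must be > 0, got {c0!r}")
    v_r = geometry.receiver_volume_ml(direction)
    return (v_r / (geometry.membrane_area_cm2 * c0)) * slope_conc_per_min \
        / SECONDS_PER_MINUTE


def recovery_fraction(series: WellTimeSeries, cumulative: CumulativeSeries,
                      geometry: Optional[TranswellGeometry] = None) -> Optional[float]:
    """Fraction of dosed mass accounted for at assay end (donor + receiver).

    ``(C_donor_end * V_D + corrected_receiver_end * V_R) / (C_donor_0 * V_D)``;
    the sampling-corrected final receiver concentration already counts the
    mass carried away in aliquots. Returns ``None`` when the endpoint donor
    concentration was not measured ("recovery unavailable").
    """
    if series.donor_end_concentration is None:
        return None
    geometry = geometry or series.design.geometry
    v_d = geometry.donor_volume_ml(series.design.direction)
    v_r = geometry.receiver_volume_ml(series.design.direction)
    quant = np.flatnonzero(cumulative.quantifiable)
    receiver_end = cumulative.corrected[quant[-1]] if len(quant) else 0.0
    dosed = series.donor_start_concentration * v_d
    recovered = series.donor_end_concentration * v_d + receiver_end * v_r
    return recovered / dosed


def recovery_fraction_ledger(series: WellTimeSeries,
                             geometry: Optional[TranswellGeometry] = None
                             ) -> Optional[float]:
    """Recovery computed from an explicit per-aliquot mass ledger.

    Tracks the mass withdrawn in every aliquot (``V_s * measured``) plus the
    mass resident in the receiver at the end, instead of relying on the
    cumulative-corrected endpoint; equal to :func:`recovery_fraction` by the
    correction identity, and asserted so in the test suite.
    """
    if series.donor_end_concentration is None:
        return None
    geometry = geometry or series.design.geometry
    v_d = geometry.donor_volume_ml(series.design.direction)
    v_r = geometry.receiver_volume_ml(series.design.direction)
    v_s = geometry.sample_volume_ml
    quantified = [p.concentration for p in series.receiver_measurements
                  if not p.below_loq]
    if quantified:
        # receiver-side mass = resident at the final read + all prior aliquots
        receiver_mass = quantified[-1] * v_r + v_s * sum(quantified[:-1])
    else:
        receiver_mass = 0.0
    dosed = series.donor_start_concentration * v_d
    return (series.donor_end_concentration * v_d + receiver_mass) / dosed


def papp_corrected(papp_unc: float, recovery: float,
                   recovery_upper_bound: float = 1.2) -> Tuple[float, List[str]]:
    """Recovery-corrected permeability, ``Papp_uncorrected / recovery``.

    ``recovery`` is a fraction (1.0 = complete mass balance). Returns the
    value plus any QC warnings (recovery above the configured bound signals
    an implausible mass balance but does not abort the estimate).
    """
    if not math.isfinite(recovery) or recovery <= 0:
        raise ValidationError(f"recovery must be > 0, got {recovery!r}")
    warnings = []
    if recovery > recovery_upper_bound:
        warnings.append(f"recovery {recovery:.3f} exceeds bound {recovery_upper_bound:g}")
    return papp_unc / recovery, warnings


def estimate_papp(series: WellTimeSeries,
                  config: PappConfig = PappConfig()) -> PappResult:
    """Full per-well chain: cumulative correction, slope, Papp, recovery.

    Wells with fewer than ``config.min_points`` quantifiable receiver points
    return status BLQ with all permeability fields unset. A missing endpoint
    donor concentration downgrades the corrected estimate to the uncorrected
    one with an explicit warning.
    """
    cumulative = correct_cumulative(series)
    fit = fit_transfer_slope(cumulative, config.mode, config.min_points)
    if fit is None:
        logger.info("well %s: %d quantifiable points < %d -> BLQ",
                    series.well_id, int(cumulative.quantifiable.sum()), config.min_points)
        return PappResult(well_id=series.well_id, status=PappStatus.BLQ,
                          n_quantifiable_points=int(cumulative.quantifiable.sum()))

    unc = papp_uncorrected(fit.slope, series.donor_start_concentration,
                           series.design.geometry, series.design.direction)
    recovery = recovery_fraction(series, cumulative)
    warnings: List[str] = []
    if recovery is None:
        corrected = unc
        warnings.append("recovery unavailable (no endpoint donor measurement); "
                        "papp_corrected = papp_uncorrected")
    else:
        corrected, warnings = papp_corrected(unc, recovery, config.recovery_upper_bound)
    return PappResult(
        well_id=series.well_id, status=PappStatus.OK, slope=fit.slope,
        intercept=fit.intercept, r_squared=fit.r_squared,
        papp_uncorrected=unc, recovery_fraction=recovery,
        papp_corrected=corrected,
        n_quantifiable_points=int(cumulative.quantifiable.sum()),
        warnings=warnings)


def efflux_ratio(ab: Union[PappResult, float], ba: Union[PappResult, float],
                 threshold: float = 2.0) -> Optional[EffluxAssessment]:
    """Secretory/absorptive permeability ratio with the conventional >2 call.

    ``ratio = Papp(BL->AP) / Papp(AP->BL)``. Returns ``None`` when either
    direction is BLQ (ratio undefined).
    """
    def _value(x):
        if isinstance(x, PappResult):
            if x.status is not PappStatus.OK or x.papp_corrected is None:
                return None
            return x.papp_corrected
        return float(x)

    a, b = _value(ab), _value(ba)
    if a is None or b is None:
        return None
    if a <= 0:
        raise ValidationError("absorptive Papp must be > 0 to form a ratio")
    ratio = b / a
    return EffluxAssessment(papp_ab=a, papp_ba=b, ratio=ratio,
                            active_efflux_flag=ratio > threshold)


def summarize_condition(results: Sequence[PappResult],
                        key: Optional[dict] = None) -> Optional[ConditionSummary]:
    """Mean / sample SD / SEM / CV% of corrected Papp over OK wells.

    Groups of size one report the mean only; empty groups are skipped with a
    log entry and return ``None``.
    """
    values = [r.papp_corrected for r in results
              if r.status is PappStatus.OK and r.papp_corrected is not None]
    if not values:
        logger.info("condition %s: no OK wells, skipped", key)
        return None
    n = len(values)
    mean = float(np.mean(values))
    if n >= 2:
        sd = float(np.std(values, ddof=1))
        sem = sd / math.sqrt(n)
        cv = 100.0 * sd / mean if mean != 0 else None
    else:
        sd = sem = cv = None
    return ConditionSummary(key=dict(key or {}), values=list(values), n=n,
                            mean=mean, sd=sd, sem=sem, cv_percent=cv)


def summarize_by(results: Sequence[PappResult], series: Sequence[WellTimeSeries],
                 ) -> List[ConditionSummary]:
    """Group per-well results by (drug, dose, direction, pH pair, system)."""
    by_well = {s.well_id: s for s in series}
    groups: Dict[tuple, List[PappResult]] = {}
    for r in results:
        d = by_well[r.well_id].design
        key = (d.drug.name, d.donor_concentration_mg_ml, d.direction.value,
               d.apical_ph, d.basolateral_ph, d.system.value)
        groups.setdefault(key, []).append(r)
    out = []
    for key in sorted(groups):
        summary = summarize_condition(groups[key], key={
            "drug": key[0], "donor_concentration_mg_ml": key[1],
            "direction": key[2], "apical_ph": key[3], "basolateral_ph": key[4],
            "system": key[5]})
        if summary is not None:
            out.append(summary)
    return out


def display_round(papp_cm_s: float, decimals: int = 2) -> float:
    """Half-up rounding on the 1e-6 cm/s display scale used in reports."""
    import decimal
    scaled = decimal.Decimal(repr(float(papp_cm_s) * 1e6))
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(scaled.quantize(q, rounding=decimal.ROUND_HALF_UP))
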