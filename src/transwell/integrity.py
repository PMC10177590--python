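"""Barrier-integrity QC: TEER normalization and gating, FITC-dextran leakage.

Monolayer integrity is judged two ways before a well enters the permeability
analysis:

* **TEER** -- daily raw resistances are blank-subtracted and scaled by the
  membrane area (``(R_sample - R_blank) * A``); the trajectory must reach a
  steady-state plateau at or above a system-specific threshold
  (500 Ohm*cm2 for Caco-2, 4000 Ohm*cm2 for colonoid-derived monolayers).
* **FITC-dextran** -- a 4 kDa zero-permeability fluorescent tracer; the
  baseline-subtracted receiver %RFU must stay below a small threshold
  (default 0.02%) over the assay.

"Steady state" is operationalized as every successive relative change within
``rel_tol`` (default 5%) across a ``window_days``-long window (default 3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .model import System, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MEMBRANE_AREA_CM2 = 0.33

#: Minimum steady-state TEER (Ohm*cm2) required per culture system.
GATE_THRESHOLDS_OHM_CM2: Dict[System, float] = {
    System.CACO2: 500.0,
    System.COLONOID: 4000.0,
}

#: Literature reference points for leaky vs tight epithelia, reported as
#: annotation only (never used to gate).
EPITHELIUM_REFERENCE_OHM_CM2 = {"leaky": 100.0, "tight": 2000.0}


def normalize_teer(raw_ohm: float, blank_ohm: float,
                   area_cm2: float = DEFAULT_MEMBRANE_AREA_CM2) -> float:
    """Blank-subtracted, area-scaled resistance: ``(raw - blank) * area``.

    A negative result (sample below blank) is allowed but should be flagged
    by the caller; it is physically suspect, not fatal.
    """
    if area_cm2 <= 0:
        raise ValidationError(f"membrane area must be > 0, got {area_cm2!r}")
    return (raw_ohm - blank_ohm) * area_cm2


@dataclass
class TEERSeries:
    """Daily resistance readings for one monolayer."""

    well_id: str
    system: System
    days: np.ndarray
    raw_ohm: np.ndarray
    blank_ohm: np.ndarray
    membrane_area_cm2: float = DEFAULT_MEMBRANE_AREA_CM2

    def __post_init__(self) -> None:
        self.system = System.parse(self.system)
        self.days = np.asarray(self.days, dtype=float)
        self.raw_ohm = np.asarray(self.raw_ohm, dtype=float)
        self.blank_ohm = np.asarray(self.blank_ohm, dtype=float)
        if not (len(self.days) == len(self.raw_ohm) == len(self.blank_ohm)):
            raise ValidationError("days, raw and blank arrays must share length")

    @property
    def normalized(self) -> np.ndarray:
        return (self.raw_ohm - self.blank_ohm) * self.membrane_area_cm2

    @property
    def below_blank_days(self) -> np.ndarray:
        """Days whose raw reading fell below the blank (flag, not fatal)."""
        return self.days[self.raw_ohm < self.blank_ohm]


@dataclass
class IntegrityVerdict:
    """Outcome of the TEER (and optionally leakage) gate for one monolayer."""

    well_id: str
    system: System
    plateau_day: Optional[float]
    plateau_mean: Optional[float]
    gate_threshold: float
    passed: bool
    leakage_passed: Optional[bool] = None  # None = not assessed


def detect_plateau(days: Sequence[float], normalized: Sequence[float],
                   window_days: int = 3, rel_tol: float = 0.05
                   ) -> Tuple[Optional[float], Optional[float]]:
    """Earliest steady-state window of the normalized TEER trajectory.

    Returns ``(plateau_day, plateau_mean)`` for the first window of
    ``window_days`` consecutive readings whose successive relative changes
    are all within ``rel_tol``; ``(None, None)`` when no such window exists
    or the series is too short.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(normalized, dtype=float)
    if len(values) < window_days:
        logger.info("TEER series shorter than plateau window (%d < %d)",
                    len(values), window_days)
        return None, None
    for start in range(0, len(values) - window_days + 1):
        window = values[start:start + window_days]
        ref = window[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(np.diff(window)) / np.abs(ref)
        rel = np.where(ref == 0, np.where(np.diff(window) == 0, 0.0, np.inf), rel)
        if np.all(rel <= rel_tol):
            return float(days[start]), float(window.mean())
    return None, None


def gate_monolayer(well_id: str, plateau_day: Optional[float],
                   plateau_mean: Optional[float],
                   system: Union[System, str],
                   thresholds: Optional[Dict[System, float]] = None,
                   leakage_passed: Optional[bool] = None) -> IntegrityVerdict:
    """Pass/fail the monolayer against its system-specific TEER threshold.

    The comparison is inclusive (``>=``): a plateau mean exactly at the
    threshold passes. A monolayer with no detected plateau fails.
    """
    system = System.parse(system)
    thresholds = thresholds or GATE_THRESHOLDS_OHM_CM2
    try:
        threshold = thresholds[system]
    except KeyError:
        raise ValidationError(f"no gate threshold for system {system!r}") from None
    passed = plateau_day is not None and plateau_mean is not None \
        and plateau_mean >= threshold
    return IntegrityVerdict(well_id=well_id, system=system,
                            plateau_day=plateau_day, plateau_mean=plateau_mean,
                            gate_threshold=threshold, passed=bool(passed),
                            leakage_passed=leakage_passed)


def assess_teer(series: TEERSeries, window_days: int = 3, rel_tol: float = 0.05,
                thresholds: Optional[Dict[System, float]] = None) -> IntegrityVerdict:
    """Convenience: plateau detection followed by gating for one series."""
    day, mean = detect_plateau(series.days, series.normalized,
                               window_days=window_days, rel_tol=rel_tol)
    return gate_monolayer(series.well_id, day, mean, series.system,
                          thresholds=thresholds)


@dataclass
class FluorescenceSeries:
    """Donor/receiver fluorescence readings for a tracer-leakage assay."""

    times_min: np.ndarray
    receiver_rfu: np.ndarray
    donor_initial_rfu: float
    donor_rfu: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.receiver_rfu = np.asarray(self.receiver_rfu, dtype=float)
        if np.any(self.receiver_rfu < 0) or (
                self.donor_rfu is not None and np.any(np.asarray(self.donor_rfu) < 0)):
            raise ValidationError("RFU values must be >= 0")


def fitc_leakage(series: FluorescenceSeries,
                 threshold_percent: float = 0.02
                 ) -> Tuple[np.ndarray, float, bool]:
    """Tracer transport as baseline-subtracted receiver %RFU.

    ``%RFU(t) = 100 * RFU_receiver(t) / donor_initial_rfu``; transport is the
    maximum rise of receiver %RFU above its time-zero baseline (the receiver
    reads a small background even before any leakage, so the absolute level
    is not the right criterion). Passes when transport < ``threshold_percent``.

    Returns ``(receiver %RFU per time, transport, passed)``.
    """
    if not (math.isfinite(series.donor_initial_rfu) and series.donor_initial_rfu > 0):
        raise ValidationError("donor_initial_rfu must be > 0")
    percent = 100.0 * series.receiver_rfu / series.donor_initial_rfu
    transport = float(np.max(percent - percent[0]))
    return percent, transport, transport < threshold_percent
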