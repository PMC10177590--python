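"""Core domain types for bidirectional Transwell permeability assays.

The objects here describe one dual-chamber diffusion experiment: the insert
geometry (membrane area, chamber volumes, serial-sampling volume), the dosed
drug, the per-well assay design (direction, pH pair, sampling schedule) and
the measured receiver-concentration time series with below-LOQ censoring.
All downstream stages (simulation, Papp estimation, QC, reporting) consume
and produce these types.

Unit conventions
----------------
* volumes in mL, areas in cm2, times in minutes;
* concentrations in a single consistent mass/volume unit per experiment
  (mg/mL throughout the bundled workflows);
* apparent permeability always reported in cm/s.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


class ValidationError(ValueError):
    """An input violates a structural invariant of the assay model."""


class SchemaError(ValidationError):
    """A tabular input is missing or misusing a required column."""


class UnknownWellError(LookupError):
    """A well identifier does not resolve to any assay design."""


class Direction(str, enum.Enum):
    """Transport direction across the monolayer."""

    AP_TO_BL = "AP_to_BL"  # absorptive: apical donor, basolateral receiver
    BL_TO_AP = "BL_to_AP"  # secretive: basolateral donor, apical receiver

    @classmethod
    def parse(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, cls):
            return value
        text = str(value).strip()
        for member in cls:
            if text.lower() in (member.value.lower(), member.name.lower()):
                return member
        aliases = {"a-b": cls.AP_TO_BL, "ap-bl": cls.AP_TO_BL, "a2b": cls.AP_TO_BL,
                   "b-a": cls.BL_TO_AP, "bl-ap": cls.BL_TO_AP, "b2a": cls.BL_TO_AP}
        try:
            return aliases[text.lower()]
        except KeyError:
            raise ValidationError(f"unrecognized transport direction: {value!r}") from None


class System(str, enum.Enum):
    """Cell culture system forming the monolayer."""

    COLONOID = "colonoid"
    CACO2 = "caco2"

    @classmethod
    def parse(cls, value: "System | str") -> "System":
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        for member in cls:
            if text == member.value:
                return member
        aliases = {"caco-2": cls.CACO2, "human": cls.CACO2,
                   "dog": cls.COLONOID, "canine": cls.COLONOID}
        try:
            return aliases[text]
        except KeyError:
            raise ValidationError(f"unrecognized culture system: {value!r}") from None


@dataclass(frozen=True)
class TranswellGeometry:
    """Physical geometry of one Transwell insert and its sampling protocol.

    Defaults describe a 24-well-format insert: 0.33 cm2 membrane, 0.2 mL
    apical and 0.7 mL basolateral chamber, with 100 uL receiver aliquots
    withdrawn at each sampling time and replaced with blank buffer.
    """

    membrane_area_cm2: float = 0.33
    apical_volume_ml: float = 0.2
    basolateral_volume_ml: float = 0.7
    sample_volume_ml: float = 0.1
    replacement: bool = True

    def __post_init__(self) -> None:
        for name in ("membrane_area_cm2", "apical_volume_ml",
                     "basolateral_volume_ml", "sample_volume_ml"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")

    def donor_volume_ml(self, direction: Direction) -> float:
        direction = Direction.parse(direction)
        return (self.apical_volume_ml if direction is Direction.AP_TO_BL
                else self.basolateral_volume_ml)

    def receiver_volume_ml(self, direction: Direction) -> float:
        direction = Direction.parse(direction)
        return (self.basolateral_volume_ml if direction is Direction.AP_TO_BL
                else self.apical_volume_ml)


@dataclass(frozen=True)
class DrugSpec:
    """Physicochemical identity of a dosed compound.

    ``salt_factor`` is the ratio of the dosed salt's molecular weight to the
    free-base molecular weight; 1.0 when the compound is dosed as free base.
    Molar conversions divide by ``molecular_weight_freebase * salt_factor``
    so that the reported molarity refers to the dosed species.
    """

    name: str
    molecular_weight_freebase: float  # g/mol
    salt_factor: float = 1.0
    logp: Optional[float] = None
    pka_basic: Optional[float] = None
    aqueous_solubility_mg_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.molecular_weight_freebase)
                and self.molecular_weight_freebase > 0):
            raise ValidationError(
                f"molecular_weight_freebase must be > 0, got {self.molecular_weight_freebase!r}")
        if not (math.isfinite(self.salt_factor) and self.salt_factor >= 1.0):
            raise ValidationError(f"salt_factor must be >= 1, got {self.salt_factor!r}")


def mg_per_ml_to_micromolar(c_mg_per_ml: float, drug: DrugSpec) -> float:
    """Convert a mass concentration (mg/mL) to micromolar for a dosed drug.

    Returns ``c / (MW_freebase * salt_factor) * 1e6`` -- the molarity in uM
    of the dosed species (salt-corrected when ``salt_factor > 1``).
    """
    if c_mg_per_ml < 0:
        raise ValidationError(f"concentration must be >= 0, got {c_mg_per_ml!r}")
    mw = drug.molecular_weight_freebase * drug.salt_factor
    return c_mg_per_ml / mw * 1e6


DEFAULT_SAMPLING_TIMES_MIN = (15.0, 30.0, 45.0, 60.0, 90.0, 120.0)


@dataclass(frozen=True)
class AssayDesign:
    """One well's experimental design: drug, dose, direction, pH pair,
    geometry, culture system, and serial-sampling schedule."""

    drug: DrugSpec
    donor_concentration_mg_ml: float
    direction: Direction
    apical_ph: float = 6.8
    basolateral_ph: float = 7.4
    geometry: TranswellGeometry = field(default_factory=TranswellGeometry)
    sampling_times_min: tuple = DEFAULT_SAMPLING_TIMES_MIN
    system: System = System.CACO2

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction.parse(self.direction))
        object.__setattr__(self, "system", System.parse(self.system))
        object.__setattr__(self, "sampling_times_min",
                           tuple(float(t) for t in self.sampling_times_min))
        if self.donor_concentration_mg_ml <= 0:
            raise ValidationError("donor_concentration_mg_ml must be > 0")
        times = self.sampling_times_min
        if len(times) == 0:
            raise ValidationError("sampling_times_min must be non-empty")
        if times[0] <= 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"sampling times must be strictly increasing and > 0: {times}")
        for name, ph in (("apical_ph", self.apical_ph), ("basolateral_ph", self.basolateral_ph)):
            if not (0.0 <= ph <= 14.0):
                raise ValidationError(f"{name} out of range [0, 14]: {ph}")
        if self.geometry.sample_volume_ml >= self.geometry.receiver_volume_ml(self.direction):
            raise ValidationError(
                "sample_volume_ml must be smaller than the receiver chamber volume")

    @property
    def donor_volume_ml(self) -> float:
        return self.geometry.donor_volume_ml(self.direction)

    @property
    def receiver_volume_ml(self) -> float:
        return self.geometry.receiver_volume_ml(self.direction)


@dataclass(frozen=True)
class ReceiverPoint:
    """One receiver-chamber measurement: time, concentration, censoring flag.

    ``concentration`` is NaN when the point is below the limit of
    quantification (``below_loq`` True); a measured 0.0 is a valid value and
    is distinct from a censored point.
    """

    time_min: float
    concentration: float
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.below_loq:
            return
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValidationError(
                f"non-censored concentration must be finite and >= 0, "
                f"got {self.concentration!r} at t={self.time_min}")


@dataclass
class WellTimeSeries:
    """Measured concentrations for one well over the sampling schedule.

    Donor concentration is measured only at t = 0 (``donor_start``) and the
    final sampling time (``donor_end``); receiver concentrations are measured
    at each scheduled time, censored below ``loq``.
    """

    well_id: str
    design: AssayDesign
    receiver_measurements: list  # list[ReceiverPoint]
    donor_start_concentration: float
    donor_end_concentration: Optional[float] = None
    loq: float = float("nan")

    def __post_init__(self) -> None:
        pts = list(self.receiver_measurements)
        times = [p.time_min for p in pts]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"well {self.well_id}: receiver times must be strictly increasing: {times}")
        allowed = set(self.design.sampling_times_min)
        extra = [t for t in times if t not in allowed]
        if extra:
            raise ValidationError(
                f"well {self.well_id}: times {extra} not in design sampling schedule")
        if not (math.isfinite(self.donor_start_concentration)
                and self.donor_start_concentration > 0):
            raise ValidationError(
                f"well {self.well_id}: donor_start_concentration must be > 0")
        self.receiver_measurements = pts

    @property
    def times(self) -> list:
        return [p.time_min for p in self.receiver_measurements]

    @property
    def n_quantifiable(self) -> int:
        return sum(1 for p in self.receiver_measurements if not p.below_loq)


class PappStatus(str, enum.Enum):
    OK = "OK"
    BLQ = "BLQ"
    FAILED_QC = "FAILED_QC"


@dataclass
class PappResult:
    """Per-well apparent-permeability estimate and its provenance.

    ``papp_corrected = papp_uncorrected / recovery_fraction`` whenever the
    status is OK and recovery is available; when the well has too few
    quantifiable receiver points the status is BLQ and all permeability
    fields are None.
    """

    well_id: str
    status: PappStatus
    slope: Optional[float] = None              # concentration / min
    intercept: Optional[float] = None
    r_squared: Optional[float] = None
    papp_uncorrected: Optional[float] = None   # cm/s
    recovery_fraction: Optional[float] = None
    papp_corrected: Optional[float] = None     # cm/s
    n_quantifiable_points: int = 0
    warnings: list = field(default_factory=list)


@dataclass
class ConditionSummary:
    """Descriptive statistics of corrected Papp over replicate wells of one
    experimental condition (drug, dose, direction, pH pair, system)."""

    key: dict
    values: list
    n: int
    mean: float
    sd: Optional[float]          # sample SD, n-1 denominator; None for n < 2
    sem: Optional[float]
    cv_percent: Optional[float]  # 100 * sd / mean
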