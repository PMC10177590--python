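"""Mechanistic generators for synthetic Transwell, TEER, and qPCR data.

``simulate_well`` integrates passive two-compartment diffusion across the
monolayer at a known true permeability, with serial receiver sampling
(aliquot removal and blank-buffer replacement), optional first-order
nonspecific loss, multiplicative lognormal measurement noise, and censoring
below the limit of quantification. Because the exchange is linear, the state
is propagated *exactly* between sampling events with the matrix exponential
of the 2x2 rate matrix, so integrator error never enters parameter-recovery
comparisons.

The generator's defaults mirror the bench protocol the analysis targets:
0.33 cm2 inserts, 0.2/0.7 mL chambers, 100 uL aliquots at
15/30/45/60/90/120 min replaced with blank buffer, donor concentration
measured at 0 and 120 min only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .model import (
    AssayDesign,
    Direction,
    DrugSpec,
    ReceiverPoint,
    System,
    TranswellGeometry,
    ValidationError,
    WellTimeSeries,
    DEFAULT_SAMPLING_TIMES_MIN,
)

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class DiffusionSimParams:
    """Parameters of one simulated diffusion well.

    ``papp_true_cm_s`` is the ground-truth apparent permeability the analysis
    pipeline should recover. ``noise_cv`` is the coefficient of variation of
    mean-one multiplicative lognormal measurement noise (0.05 reflects a
    bioanalytical assay holding QC bias within 10%). ``loss_rate_per_min``
    applies first-order nonspecific loss to both chambers.
    """

    papp_true_cm_s: float
    donor_concentration_0: float = 0.4           # mg/mL, mid-range dose
    direction: Direction = Direction.AP_TO_BL
    geometry: TranswellGeometry = field(default_factory=TranswellGeometry)
    sampling_times_min: tuple = DEFAULT_SAMPLING_TIMES_MIN
    noise_cv: float = 0.05
    loq: float = 0.0                             # same unit as concentrations
    loss_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.papp_true_cm_s < 0:
            raise ValidationError("papp_true_cm_s must be >= 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.loss_rate_per_min < 0:
            raise ValidationError("loss_rate_per_min must be >= 0")
        if self.donor_concentration_0 <= 0:
            raise ValidationError("donor_concentration_0 must be > 0")
        if self.loq < 0:
            raise ValidationError("loq must be >= 0")


@dataclass
class WellTruth:
    """Noiseless ground-truth trajectory for one simulated well."""

    papp_true_cm_s: float
    times_min: np.ndarray
    donor_concentration: np.ndarray       # true donor conc at each sampling time
    receiver_concentration_pre: np.ndarray  # true pre-removal receiver conc
    sampled_mass_cumulative: np.ndarray   # mass removed in aliquots up to and incl. t
    donor_mass: np.ndarray
    receiver_mass_post: np.ndarray        # receiver mass just after sampling event
    initial_mass: float
    recovery_true: float                  # (donor + receiver + sampled) / initial at end


def _rate_matrix(papp_cm_min: float, area_cm2: float, v_donor: float,
                 v_receiver: float, loss_rate: float) -> np.ndarray:
    """Rate matrix of d/dt (M_donor, M_receiver) for linear passive exchange."""
    pa = papp_cm_min * area_cm2  # mL/min
    return np.array([
        [-pa / v_donor - loss_rate, pa / v_receiver],
        [pa / v_donor, -pa / v_receiver - loss_rate],
    ])


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise factors with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def simulate_well(params: DiffusionSimParams, well_id: str = "sim_well",
                  design: Optional[AssayDesign] = None,
                  drug: Optional[DrugSpec] = None) -> Tuple[WellTimeSeries, WellTruth]:
    """Simulate one bidirectional-transport well.

    Returns the measured (noisy, censored) ``WellTimeSeries`` together with
    the noiseless ``WellTruth`` trajectory. The measured receiver
    concentration at each sampling time reflects the chamber immediately
    before aliquot removal; removal and blank replacement are instantaneous.
    With ``loss_rate_per_min = 0`` total drug mass (donor + receiver +
    cumulative sampled aliquots) is conserved exactly.
    """
    geom = params.geometry
    direction = Direction.parse(params.direction)
    v_d = geom.donor_volume_ml(direction)
    v_r = geom.receiver_volume_ml(direction)
    v_s = geom.sample_volume_ml
    if v_s >= v_r:
        raise ValidationError("sample volume must be smaller than receiver volume")
    papp_cm_min = params.papp_true_cm_s * SECONDS_PER_MINUTE

    rng = np.random.default_rng(params.seed)
    times = np.asarray(params.sampling_times_min, dtype=float)
    n = len(times)

    state = np.array([params.donor_concentration_0 * v_d, 0.0])
    initial_mass = state[0]
    sampled_cum = 0.0

    donor_conc = np.empty(n)
    receiver_pre = np.empty(n)
    sampled_cum_arr = np.empty(n)
    donor_mass = np.empty(n)
    receiver_mass_post = np.empty(n)

    noise = _lognormal_factors(rng, params.noise_cv, n + 2)  # receiver + donor 0/end
    points: List[ReceiverPoint] = []

    t_prev = 0.0
    v_r_now = v_r
    for i, t in enumerate(times):
        k = _rate_matrix(papp_cm_min, geom.membrane_area_cm2, v_d, v_r_now,
                         params.loss_rate_per_min)
        state = expm(k * (t - t_prev)) @ state
        t_prev = t

        c_r_pre = state[1] / v_r_now
        donor_conc[i] = state[0] / v_d
        receiver_pre[i] = c_r_pre

        measured = c_r_pre * noise[i]
        if measured < params.loq:
            points.append(ReceiverPoint(t, float("nan"), True))
        else:
            points.append(ReceiverPoint(t, measured, False))

        removed = v_s * c_r_pre
        state[1] -= removed
        sampled_cum += removed
        if not geom.replacement:
            v_r_now -= v_s
            if v_r_now <= 0:
                raise ValidationError("receiver volume exhausted without replacement")

        sampled_cum_arr[i] = sampled_cum
        donor_mass[i] = state[0]
        receiver_mass_post[i] = state[1]

    recovery_true = (state[0] + state[1] + sampled_cum) / initial_mass

    c0_measured = params.donor_concentration_0 * noise[n]
    donor_end_measured = donor_conc[-1] * noise[n + 1]

    if design is None:
        design = AssayDesign(
            drug=drug or DrugSpec(name="synthetic", molecular_weight_freebase=267.36),
            donor_concentration_mg_ml=params.donor_concentration_0,
            direction=direction,
            geometry=geom,
            sampling_times_min=tuple(times),
        )
    series = WellTimeSeries(
        well_id=well_id, design=design, receiver_measurements=points,
        donor_start_concentration=c0_measured,
        donor_end_concentration=donor_end_measured, loq=params.loq)
    truth = WellTruth(
        papp_true_cm_s=params.papp_true_cm_s, times_min=times,
        donor_concentration=donor_conc, receiver_concentration_pre=receiver_pre,
        sampled_mass_cumulative=sampled_cum_arr, donor_mass=donor_mass,
        receiver_mass_post=receiver_mass_post, initial_mass=initial_mass,
        recovery_true=recovery_true)
    return series, truth


def two_compartment_analytic(papp_cm_s: float, geometry: TranswellGeometry,
                             direction: Direction, c_donor_0: float,
                             c_receiver_0: float, t_min: float) -> Tuple[float, float]:
    """Closed-form lossless two-compartment solution (no sampling events).

    The concentration difference decays as ``exp(-lambda t)`` with
    ``lambda = P*A*(1/V_D + 1/V_R)`` while total mass is conserved; used as
    an independent oracle for the event-aware integrator.
    """
    v_d = geometry.donor_volume_ml(direction)
    v_r = geometry.receiver_volume_ml(direction)
    pa = papp_cm_s * SECONDS_PER_MINUTE * geometry.membrane_area_cm2
    lam = pa * (1.0 / v_d + 1.0 / v_r)
    m_tot = c_donor_0 * v_d + c_receiver_0 * v_r
    c_eq = m_tot / (v_d + v_r)
    dc = (c_donor_0 - c_receiver_0) * math.exp(-lam * t_min)
    # split the equilibrium + decaying difference back into the two chambers
    c_d = c_eq + dc * v_r / (v_d + v_r)
    c_r = c_eq - dc * v_d / (v_d + v_r)
    return c_d, c_r


# ---------------------------------------------------------------------------
# plate-level generation


@dataclass(frozen=True)
class PlateCondition:
    """One cell of the simulated condition grid."""

    drug: DrugSpec
    donor_concentration_mg_ml: float
    direction: Direction
    papp_true_cm_s: float
    system: System = System.CACO2
    apical_ph: float = 6.8
    basolateral_ph: float = 7.4
    loq: float = 0.0
    noise_cv: float = 0.05
    loss_rate_per_min: float = 0.0

    @property
    def key(self) -> tuple:
        return (self.drug.name, self.donor_concentration_mg_ml,
                Direction.parse(self.direction).value, self.apical_ph,
                self.basolateral_ph, System.parse(self.system).value)


def simulate_plate(conditions: Sequence[PlateCondition], n_wells: int,
                   seed: int, geometry: Optional[TranswellGeometry] = None,
                   sampling_times_min: tuple = DEFAULT_SAMPLING_TIMES_MIN,
                   ) -> Tuple[List[WellTimeSeries], pd.DataFrame]:
    """Simulate ``n_wells`` replicate wells for every condition in the grid.

    Deterministic for a fixed seed; well ids encode the condition. Returns
    the series collection and a truth table (one row per well).
    """
    if not conditions:
        raise ValidationError("condition grid must be non-empty")
    keys = [c.key for c in conditions]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate condition keys in grid")
    geometry = geometry or TranswellGeometry()

    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(len(conditions) * n_wells) % (2**31 - 1)

    series_all: List[WellTimeSeries] = []
    truth_rows = []
    idx = 0
    for cond in conditions:
        direction = Direction.parse(cond.direction)
        for w in range(n_wells):
            well_id = (f"{cond.drug.name}_{cond.donor_concentration_mg_ml:g}"
                       f"_{System.parse(cond.system).value}_{direction.value}"
                       f"_pH{cond.apical_ph:g}-{cond.basolateral_ph:g}_w{w + 1}")
            params = DiffusionSimParams(
                papp_true_cm_s=cond.papp_true_cm_s,
                donor_concentration_0=cond.donor_concentration_mg_ml,
                direction=direction, geometry=geometry,
                sampling_times_min=sampling_times_min,
                noise_cv=cond.noise_cv, loq=cond.loq,
                loss_rate_per_min=cond.loss_rate_per_min,
                seed=int(child_seeds[idx]))
            design = AssayDesign(
                drug=cond.drug,
                donor_concentration_mg_ml=cond.donor_concentration_mg_ml,
                direction=direction, apical_ph=cond.apical_ph,
                basolateral_ph=cond.basolateral_ph, geometry=geometry,
                sampling_times_min=tuple(sampling_times_min),
                system=System.parse(cond.system))
            s, truth = simulate_well(params, well_id=well_id, design=design)
            series_all.append(s)
            truth_rows.append({
                "well_id": well_id, "drug": cond.drug.name,
                "donor_concentration_mg_ml": cond.donor_concentration_mg_ml,
                "direction": direction.value,
                "system": System.parse(cond.system).value,
                "apical_ph": cond.apical_ph, "basolateral_ph": cond.basolateral_ph,
                "papp_true_cm_s": cond.papp_true_cm_s,
                "recovery_true": truth.recovery_true,
                "seed": int(child_seeds[idx]),
            })
            idx += 1
    return series_all, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# TEER trajectories


@dataclass(frozen=True)
class TEERSimParams:
    """Logistic growth of transepithelial resistance toward a plateau.

    The normalized trajectory is ``plateau / (1 + exp(-k (day - midpoint)))``
    plus Gaussian noise; emitted raw readings invert the blank-subtraction /
    area-scaling normalization so the analysis can be exercised end to end.
    Default plateaus: ~4200 Ohm*cm2 for colonoid monolayers (reached around
    days 10-12), ~500 Ohm*cm2 for Caco-2 (days 18-21).
    """

    plateau_ohm_cm2: float = 4200.0
    growth_rate_per_day: float = 1.0
    midpoint_day: float = 6.0
    noise_sd_ohm_cm2: float = 50.0
    n_days: int = 12
    blank_resistance_ohm: float = 120.0
    membrane_area_cm2: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_ohm_cm2 <= 0:
            raise ValidationError("plateau must be > 0")
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        if self.noise_sd_ohm_cm2 < 0:
            raise ValidationError("noise_sd must be >= 0")

    @classmethod
    def colonoid_defaults(cls, seed: int = 0) -> "TEERSimParams":
        return cls(seed=seed)

    @classmethod
    def caco2_defaults(cls, seed: int = 0) -> "TEERSimParams":
        return cls(plateau_ohm_cm2=500.0, growth_rate_per_day=0.6,
                   midpoint_day=12.0, noise_sd_ohm_cm2=10.0, n_days=23, seed=seed)


def simulate_teer_series(params: TEERSimParams) -> pd.DataFrame:
    """Emit daily raw sample/blank resistance readings for one monolayer.

    Columns: ``day, raw_ohm, blank_ohm, normalized_true_ohm_cm2``. Applying
    the standard normalization ``(raw - blank) * area`` to the emitted raw
    values recovers the noisy normalized trajectory exactly.
    """
    rng = np.random.default_rng(params.seed)
    days = np.arange(1, params.n_days + 1, dtype=float)
    logistic = params.plateau_ohm_cm2 / (
        1.0 + np.exp(-params.growth_rate_per_day * (days - params.midpoint_day)))
    noisy = logistic + rng.normal(0.0, params.noise_sd_ohm_cm2, size=len(days)) \
        if params.noise_sd_ohm_cm2 > 0 else logistic.copy()
    raw = noisy / params.membrane_area_cm2 + params.blank_resistance_ohm
    return pd.DataFrame({
        "day": days.astype(int),
        "raw_ohm": raw,
        "blank_ohm": np.full(len(days), params.blank_resistance_ohm),
        "normalized_true_ohm_cm2": logistic,
    })


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class CtSimParams:
    """Replicate Ct values distributed around gene-specific means.

    Each replicate draws a housekeeping Ct from
    ``N(housekeeping_mean, housekeeping_sd)``; every target gene's Ct is that
    draw plus its true dCt plus ``N(0, replicate_sd)`` technical noise, so
    replicate-matched normalization recovers the configured dCt exactly when
    ``replicate_sd = 0``.
    """

    true_dct: Dict[str, float] = field(default_factory=dict)
    housekeeping_gene: str = "GAPDH"
    housekeeping_mean: float = 20.67
    housekeeping_sd: float = 1.52
    replicate_sd: float = 0.3
    n_replicates: int = 3
    group: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.housekeeping_sd < 0 or self.replicate_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def simulate_ct_table(params: CtSimParams) -> pd.DataFrame:
    """Generate a long-format Ct table (group, gene, replicate, ct)."""
    rng = np.random.default_rng(params.seed)
    hk_draws = rng.normal(params.housekeeping_mean, params.housekeeping_sd,
                          size=params.n_replicates)
    rows = []
    for rep in range(params.n_replicates):
        rows.append({"group": params.group, "gene": params.housekeeping_gene,
                     "replicate": rep + 1, "ct": hk_draws[rep]})
    for gene in sorted(params.true_dct):
        noise = rng.normal(0.0, params.replicate_sd, size=params.n_replicates) \
            if params.replicate_sd > 0 else np.zeros(params.n_replicates)
        for rep in range(params.n_replicates):
            rows.append({"group": params.group, "gene": gene, "replicate": rep + 1,
                         "ct": hk_draws[rep] + params.true_dct[gene] + noise[rep]})
    return pd.DataFrame(rows)
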