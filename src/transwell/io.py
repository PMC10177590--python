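"""CSV/JSON interchange for assay designs, time series, and results.

File contracts
--------------
timeseries CSV (long format)
    columns ``well_id, compartment, time_min, concentration, unit, loq_flag``;
    ``compartment`` is ``donor`` or ``receiver``; the donor row at time 0
    supplies C_0 and the donor row at the final time supplies the endpoint
    donor concentration; ``loq_flag`` is empty or the literal token ``BLQ``
    (in which case the concentration cell may be empty or the token itself).

design table (CSV or JSON)
    one record per well with AssayDesign fields flattened; geometry columns
    are optional and fall back to the 0.33 cm2 / 0.2 mL / 0.7 mL / 0.1 mL
    defaults.

results
    ``papp_results.csv`` (per well) and ``condition_summary.csv`` (per
    condition) plus a JSON mirror; output is deterministic -- identical
    inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import math
import os
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .model import (
    AssayDesign,
    ConditionSummary,
    Direction,
    DrugSpec,
    PappResult,
    PappStatus,
    ReceiverPoint,
    SchemaError,
    System,
    TranswellGeometry,
    UnknownWellError,
    ValidationError,
    DEFAULT_SAMPLING_TIMES_MIN,
)

BLQ_TOKEN = "BLQ"

TIMESERIES_COLUMNS = ["well_id", "compartment", "time_min", "concentration", "unit", "loq_flag"]

_DESIGN_REQUIRED = ["well_id", "drug", "molecular_weight", "donor_concentration_mg_ml",
                    "direction", "system"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _fmt(x) -> str:
    """Deterministic numeric formatting for CSV output."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, float):
        return repr(float(x))  # shortest representation that round-trips exactly
    return str(x)


# ---------------------------------------------------------------------------
# designs


def read_designs(path: str) -> Dict[str, AssayDesign]:
    """Read a design table (CSV or JSON) into a mapping well_id -> AssayDesign."""
    if str(path).endswith(".json"):
        with open(path) as fh:
            records = json.load(fh)
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    _require_columns(df, _DESIGN_REQUIRED, "design table")
    designs: Dict[str, AssayDesign] = {}
    for rec in df.to_dict("records"):
        well_id = str(rec["well_id"])
        if well_id in designs:
            raise ValidationError(f"duplicate well_id in design table: {well_id}")
        drug = DrugSpec(
            name=str(rec["drug"]),
            molecular_weight_freebase=float(rec["molecular_weight"]),
            salt_factor=float(rec.get("salt_factor", 1.0) or 1.0),
        )
        geometry = TranswellGeometry(
            membrane_area_cm2=float(rec.get("membrane_area_cm2", 0.33) or 0.33),
            apical_volume_ml=float(rec.get("apical_volume_ml", 0.2) or 0.2),
            basolateral_volume_ml=float(rec.get("basolateral_volume_ml", 0.7) or 0.7),
            sample_volume_ml=float(rec.get("sample_volume_ml", 0.1) or 0.1),
        )
        times = rec.get("sampling_times_min")
        if isinstance(times, str):
            times = tuple(float(t) for t in times.split(";") if t != "")
        elif isinstance(times, (list, tuple)):
            times = tuple(float(t) for t in times)
        else:
            times = DEFAULT_SAMPLING_TIMES_MIN
        designs[well_id] = AssayDesign(
            drug=drug,
            donor_concentration_mg_ml=float(rec["donor_concentration_mg_ml"]),
            direction=Direction.parse(rec["direction"]),
            apical_ph=float(rec.get("apical_ph", 6.8) or 6.8),
            basolateral_ph=float(rec.get("basolateral_ph", 7.4) or 7.4),
            geometry=geometry,
            sampling_times_min=times,
            system=System.parse(rec["system"]),
        )
    return designs


def write_designs(designs: Dict[str, AssayDesign], path: str) -> None:
    rows = []
    for well_id in designs:
        d = designs[well_id]
        rows.append({
            "well_id": well_id,
            "drug": d.drug.name,
            "molecular_weight": d.drug.molecular_weight_freebase,
            "salt_factor": d.drug.salt_factor,
            "donor_concentration_mg_ml": d.donor_concentration_mg_ml,
            "direction": d.direction.value,
            "apical_ph": d.apical_ph,
            "basolateral_ph": d.basolateral_ph,
            "system": d.system.value,
            "membrane_area_cm2": d.geometry.membrane_area_cm2,
            "apical_volume_ml": d.geometry.apical_volume_ml,
            "basolateral_volume_ml": d.geometry.basolateral_volume_ml,
            "sample_volume_ml": d.geometry.sample_volume_ml,
            "sampling_times_min": ";".join(_fmt(t) for t in d.sampling_times_min),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# time series


def read_timeseries(path: str, designs: Dict[str, AssayDesign],
                    unit: Optional[str] = None) -> List:
    """Read a long-format concentration time-series CSV into WellTimeSeries.

    ``designs`` maps well ids to their AssayDesign; every well in the file
    must resolve. Rows flagged ``BLQ`` become censored receiver points.
    """
    from .model import WellTimeSeries  # local import keeps module load light

    df = pd.read_csv(path, dtype={"loq_flag": str}, keep_default_na=True,
                     float_precision="round_trip")
    _require_columns(df, TIMESERIES_COLUMNS[:4], "timeseries CSV")
    series: List[WellTimeSeries] = []
    for well_id, grp in df.groupby("well_id", sort=True):
        well_id = str(well_id)
        if well_id not in designs:
            raise UnknownWellError(f"well_id {well_id!r} not present in the design table")
        design = designs[well_id]
        donor = grp[grp["compartment"] == "donor"].sort_values("time_min")
        receiver = grp[grp["compartment"] == "receiver"]
        times = receiver["time_min"].to_numpy(dtype=float)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"well {well_id}: receiver times are not strictly increasing")
        points = []
        for rec in receiver.to_dict("records"):
            flag = str(rec.get("loq_flag", "") or "")
            raw = rec["concentration"]
            is_blq = flag.strip().upper() == BLQ_TOKEN or (
                isinstance(raw, str) and raw.strip().upper() == BLQ_TOKEN)
            if is_blq:
                points.append(ReceiverPoint(float(rec["time_min"]), float("nan"), True))
            else:
                points.append(ReceiverPoint(float(rec["time_min"]), float(raw), False))
        if donor.empty:
            raise ValidationError(f"well {well_id}: no donor rows (C_0 missing)")
        donor_recs = donor.to_dict("records")
        c0 = float(donor_recs[0]["concentration"])
        if float(donor_recs[0]["time_min"]) != 0.0:
            raise ValidationError(f"well {well_id}: first donor row must be at time 0")
        donor_end = None
        if len(donor_recs) > 1:
            donor_end = float(donor_recs[-1]["concentration"])
        loq = float("nan")
        if "loq" in grp.columns:
            loq_vals = grp["loq"].dropna()
            if len(loq_vals):
                loq = float(loq_vals.iloc[0])
        series.append(WellTimeSeries(
            well_id=well_id, design=design, receiver_measurements=points,
            donor_start_concentration=c0, donor_end_concentration=donor_end, loq=loq))
    return series


def write_timeseries(series: Iterable, path: str, unit: str = "mg/mL") -> None:
    """Write WellTimeSeries collection back to the long-format CSV."""
    rows = []
    for s in series:
        rows.append({"well_id": s.well_id, "compartment": "donor", "time_min": 0.0,
                     "concentration": _fmt(s.donor_start_concentration),
                     "unit": unit, "loq_flag": "", "loq": _fmt(s.loq)})
        for p in s.receiver_measurements:
            rows.append({"well_id": s.well_id, "compartment": "receiver",
                         "time_min": p.time_min,
                         "concentration": BLQ_TOKEN if p.below_loq else _fmt(p.concentration),
                         "unit": unit,
                         "loq_flag": BLQ_TOKEN if p.below_loq else "",
                         "loq": _fmt(s.loq)})
        if s.donor_end_concentration is not None:
            rows.append({"well_id": s.well_id, "compartment": "donor",
                         "time_min": s.receiver_measurements[-1].time_min if
                         s.receiver_measurements else 0.0,
                         "concentration": _fmt(s.donor_end_concentration),
                         "unit": unit, "loq_flag": "", "loq": _fmt(s.loq)})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results


def results_frame(results: Sequence[PappResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "well_id": r.well_id,
            "status": r.status.value,
            "slope_conc_per_min": _fmt(r.slope),
            "r_squared": _fmt(r.r_squared),
            "papp_uncorrected_cm_s": _fmt(r.papp_uncorrected),
            "recovery_fraction": _fmt(r.recovery_fraction),
            "papp_corrected_cm_s": _fmt(r.papp_corrected),
            "n_quantifiable_points": r.n_quantifiable_points,
            "warnings": ";".join(r.warnings),
        })
    return pd.DataFrame(rows, columns=[
        "well_id", "status", "slope_conc_per_min", "r_squared",
        "papp_uncorrected_cm_s", "recovery_fraction", "papp_corrected_cm_s",
        "n_quantifiable_points", "warnings"])


def summaries_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dict(s.key)
        row.update({
            "n": s.n,
            "mean_papp_cm_s": _fmt(s.mean),
            "sd_papp_cm_s": _fmt(s.sd),
            "sem_papp_cm_s": _fmt(s.sem),
            "cv_percent": _fmt(s.cv_percent),
        })
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: Sequence[PappResult], summaries: Sequence[ConditionSummary],
                  outdir: str) -> dict:
    """Write per-well and per-condition result tables (CSV + JSON mirror).

    Returns the paths written. Re-running on identical inputs is
    byte-identical.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "papp_results_csv": os.path.join(outdir, "papp_results.csv"),
        "condition_summary_csv": os.path.join(outdir, "condition_summary.csv"),
        "results_json": os.path.join(outdir, "results.json"),
    }
    results_frame(results).to_csv(paths["papp_results_csv"], index=False)
    summaries_frame(summaries).to_csv(paths["condition_summary_csv"], index=False)
    payload = {
        "papp_results": [
            {"well_id": r.well_id, "status": r.status.value, "slope": r.slope,
             "r_squared": r.r_squared, "papp_uncorrected": r.papp_uncorrected,
             "recovery_fraction": r.recovery_fraction, "papp_corrected": r.papp_corrected,
             "n_quantifiable_points": r.n_quantifiable_points, "warnings": r.warnings}
            for r in results],
        "condition_summaries": [
            {"key": s.key, "n": s.n, "values": s.values, "mean": s.mean,
             "sd": s.sd, "sem": s.sem, "cv_percent": s.cv_percent}
            for s in summaries],
    }
    with open(paths["results_json"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
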