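"""End-to-end pipeline: simulate/load -> integrity gate -> Papp -> report.

A run is described by a :class:`RunConfig` (deserializable from YAML/JSON).
Wells whose monolayer fails the TEER integrity gate are excluded from
permeability estimation, and every exclusion is listed with its reason in
the emitted ``report.md``. The report's provenance block records every
effective parameter, including defaults, so a run is reproducible from the
report alone. No stage mutates another stage's input files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import io as twio
from .bioanalysis import loq_ug_ml
from .datasets import DRUGS
from .expression import CtTable, compare_groups, delta_ct
from .integrity import (GATE_THRESHOLDS_OHM_CM2, IntegrityVerdict, TEERSeries,
                        assess_teer)
from .model import DrugSpec, PappStatus, System, TranswellGeometry, ValidationError
from .permeability import (PappConfig, SlopeMode, display_round, estimate_papp,
                           summarize_by)
from .simulate import PlateCondition, simulate_plate

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is inconsistent or incomplete."""


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    outdir: str = "transwell_run"
    seed: int = 0
    # either simulate a plate ...
    simulate: Optional[dict] = None       # {conditions: [...], n_wells: int}
    # ... or analyze existing files
    timeseries_csv: Optional[str] = None
    design_table: Optional[str] = None
    teer_csv: Optional[str] = None
    ct_csv: Optional[str] = None
    # analysis knobs
    slope_mode: str = SlopeMode.FULL_RANGE.value
    min_points: int = 3
    recovery_upper_bound: float = 1.2
    plateau_window_days: int = 3
    plateau_rel_tol: float = 0.05
    housekeeping_gene: str = "GAPDH"
    reference_group: Optional[str] = None
    comparison_family_size: Optional[int] = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.simulate is not None and self.timeseries_csv is not None:
            raise ConfigError("config requests simulation AND real time-series "
                              "input; choose one")
        if self.simulate is None and self.timeseries_csv is None:
            raise ConfigError("config must either request simulation or point "
                              "at a time-series CSV")
        if self.timeseries_csv is not None and self.design_table is None:
            raise ConfigError("a design table is required alongside a "
                              "time-series CSV")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if not path.endswith(".json") else json.load(fh)
        return cls(**raw)

    def effective_parameters(self) -> dict:
        return dataclasses.asdict(self)


def _conditions_from_config(spec: dict) -> List[PlateCondition]:
    conditions = []
    for rec in spec.get("conditions", []):
        name = rec["drug"]
        if name in DRUGS and "molecular_weight" not in rec:
            drug = DRUGS[name]
        else:
            drug = DrugSpec(name=name,
                            molecular_weight_freebase=float(rec["molecular_weight"]),
                            salt_factor=float(rec.get("salt_factor", 1.0)))
        loq = rec.get("loq_mg_ml")
        if loq is None:
            try:
                loq = loq_ug_ml(name) * 1e-3  # ug/mL -> mg/mL
            except ValidationError:
                loq = 0.0
        conditions.append(PlateCondition(
            drug=drug,
            donor_concentration_mg_ml=float(rec["donor_concentration_mg_ml"]),
            direction=rec.get("direction", "AP_to_BL"),
            papp_true_cm_s=float(rec["papp_true_cm_s"]),
            system=rec.get("system", "caco2"),
            apical_ph=float(rec.get("apical_ph", 6.8)),
            basolateral_ph=float(rec.get("basolateral_ph", 7.4)),
            loq=float(loq),
            noise_cv=float(rec.get("noise_cv", 0.05)),
            loss_rate_per_min=float(rec.get("loss_rate_per_min", 0.0))))
    if not conditions:
        raise ConfigError("simulation requested but no conditions given")
    return conditions


def _read_teer(path: str) -> List[TEERSeries]:
    df = pd.read_csv(path)
    required = {"well_id", "day", "raw_ohm", "blank_ohm", "system"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"TEER CSV missing column(s): {sorted(missing)}")
    out = []
    for well_id, grp in df.groupby("well_id", sort=True):
        grp = grp.sort_values("day")
        out.append(TEERSeries(well_id=str(well_id),
                              system=System.parse(grp["system"].iloc[0]),
                              days=grp["day"].to_numpy(),
                              raw_ohm=grp["raw_ohm"].to_numpy(),
                              blank_ohm=grp["blank_ohm"].to_numpy()))
    return out


@dataclass
class RunReport:
    config: RunConfig
    papp_results: list
    summaries: list
    verdicts: List[IntegrityVerdict]
    exclusions: List[dict]
    expression: Optional[pd.DataFrame]
    paths: dict


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured pipeline and write the report bundle."""
    os.makedirs(config.outdir, exist_ok=True)
    paths: Dict[str, str] = {}

    # --- stage 1: obtain time series -------------------------------------
    if config.simulate is not None:
        conditions = _conditions_from_config(config.simulate)
        n_wells = int(config.simulate.get("n_wells", 2))
        series, truth = simulate_plate(conditions, n_wells=n_wells, seed=config.seed)
        inputs_dir = os.path.join(config.outdir, "inputs")
        os.makedirs(inputs_dir, exist_ok=True)
        paths["timeseries_csv"] = os.path.join(inputs_dir, "timeseries.csv")
        paths["design_csv"] = os.path.join(inputs_dir, "design.csv")
        paths["truth_csv"] = os.path.join(inputs_dir, "truth.csv")
        twio.write_timeseries(series, paths["timeseries_csv"])
        twio.write_designs({s.well_id: s.design for s in series}, paths["design_csv"])
        truth.to_csv(paths["truth_csv"], index=False)
    else:
        designs = twio.read_designs(config.design_table)
        series = twio.read_timeseries(config.timeseries_csv, designs)
        truth = None

    # --- stage 2: integrity gate ------------------------------------------
    verdicts: List[IntegrityVerdict] = []
    excluded: Dict[str, str] = {}
    if config.teer_csv:
        for teer in _read_teer(config.teer_csv):
            verdict = assess_teer(teer, window_days=config.plateau_window_days,
                                  rel_tol=config.plateau_rel_tol)
            verdicts.append(verdict)
            if not verdict.passed:
                reason = ("no TEER plateau detected" if verdict.plateau_day is None
                          else f"plateau mean {verdict.plateau_mean:.1f} Ohm*cm2 "
                               f"below gate {verdict.gate_threshold:.0f}")
                excluded[verdict.well_id] = reason
                logger.info("well %s excluded: %s", verdict.well_id, reason)

    analyzed = [s for s in series if s.well_id not in excluded]
    exclusions = [{"well_id": w, "reason": r} for w, r in sorted(excluded.items())]

    # --- stage 3: permeability --------------------------------------------
    papp_config = PappConfig(mode=SlopeMode(config.slope_mode),
                             min_points=config.min_points,
                             recovery_upper_bound=config.recovery_upper_bound)
    results = [estimate_papp(s, papp_config) for s in analyzed]
    logger.info("permeability estimated for %d wells (%d BLQ)",
                len(results),
                sum(1 for r in results if r.status is PappStatus.BLQ))
    summaries = summarize_by(results, analyzed)
    paths.update(twio.write_results(results, summaries, config.outdir))

    # --- stage 4: expression ----------------------------------------------
    expression = None
    if config.ct_csv:
        table = CtTable.read_csv(config.ct_csv, config.housekeeping_gene)
        groups = sorted(table.data["group"].unique())
        if config.reference_group and len(groups) >= 2:
            others = [g for g in groups if g != config.reference_group]
            frames = [compare_groups(table, g, config.reference_group,
                                     m=config.comparison_family_size)
                      for g in others]
            expression = pd.concat(frames, ignore_index=True)
        else:
            dct = delta_ct(table)
            expression = (dct[dct["gene"] != table.housekeeping_gene]
                          .groupby(["group", "gene"], as_index=False)
                          .agg(dct_mean=("dct", "mean"), dct_sd=("dct", "std"),
                               n=("dct", "size")))
        paths["expression_csv"] = os.path.join(config.outdir, "expression.csv")
        expression.to_csv(paths["expression_csv"], index=False)

    # --- stage 5: report ---------------------------------------------------
    paths["report_md"] = os.path.join(config.outdir, "report.md")
    _write_report_md(paths["report_md"], config, results, summaries, verdicts,
                     exclusions, expression, truth)
    return RunReport(config=config, papp_results=results, summaries=summaries,
                     verdicts=verdicts, exclusions=exclusions,
                     expression=expression, paths=paths)


def _write_report_md(path: str, config: RunConfig, results, summaries,
                     verdicts, exclusions, expression, truth) -> None:
    lines: List[str] = ["# Transwell permeability run report", ""]

    lines += ["## Provenance", "", "```yaml"]
    lines.append(yaml.safe_dump(config.effective_parameters(),
                                default_flow_style=False, sort_keys=True).rstrip())
    lines += ["```", ""]

    if verdicts:
        lines += ["## Barrier integrity (TEER gate)", "",
                  "| well | system | plateau day | plateau mean (Ohm*cm2) | gate | verdict |",
                  "|---|---|---|---|---|---|"]
        for v in verdicts:
            lines.append(
                f"| {v.well_id} | {v.system.value} | "
                f"{'-' if v.plateau_day is None else f'{v.plateau_day:g}'} | "
                f"{'-' if v.plateau_mean is None else f'{v.plateau_mean:.1f}'} | "
                f"{v.gate_threshold:.0f} | {'pass' if v.passed else 'FAIL'} |")
        lines.append("")
    if exclusions:
        lines += ["### Excluded wells", ""]
        for e in exclusions:
            lines.append(f"- `{e['well_id']}`: {e['reason']}")
        lines.append("")

    lines += ["## Per-well apparent permeability", "",
              "| well | status | Papp x 1e-6 cm/s | recovery | r^2 | notes |",
              "|---|---|---|---|---|---|"]
    for r in results:
        papp = ("BLQ" if r.status is PappStatus.BLQ
                else f"{display_round(r.papp_corrected):.2f}")
        rec = "-" if r.recovery_fraction is None else f"{r.recovery_fraction:.3f}"
        r2 = "-" if r.r_squared is None else f"{r.r_squared:.4f}"
        lines.append(f"| {r.well_id} | {r.status.value} | {papp} | {rec} | {r2} | "
                     f"{'; '.join(r.warnings) if r.warnings else ''} |")
    lines.append("")

    if summaries:
        lines += ["## Condition summaries", "",
                  "| drug | dose (mg/mL) | direction | pH (AP/BL) | system | n | "
                  "mean x 1e-6 | SD x 1e-6 | CV% |",
                  "|---|---|---|---|---|---|---|---|---|"]
        for s in summaries:
            k = s.key
            sd = "-" if s.sd is None else f"{s.sd * 1e6:.2f}"
            cv = "-" if s.cv_percent is None else f"{s.cv_percent:.2f}"
            lines.append(
                f"| {k.get('drug')} | {k.get('donor_concentration_mg_ml')} | "
                f"{k.get('direction')} | {k.get('apical_ph')}/{k.get('basolateral_ph')} | "
                f"{k.get('system')} | {s.n} | {s.mean * 1e6:.2f} | {sd} | {cv} |")
        lines.append("")

    if truth is not None:
        merged = {r.well_id: r for r in results}
        lines += ["## Parameter recovery vs simulation truth", "",
                  "| well | true Papp (cm/s) | estimated (cm/s) | rel. error |",
                  "|---|---|---|---|"]
        for rec in truth.to_dict("records"):
            r = merged.get(rec["well_id"])
            if r is None or r.status is not PappStatus.OK:
                lines.append(f"| {rec['well_id']} | {rec['papp_true_cm_s']:.3g} | BLQ | - |")
            else:
                err = (r.papp_corrected - rec["papp_true_cm_s"]) / rec["papp_true_cm_s"]
                lines.append(f"| {rec['well_id']} | {rec['papp_true_cm_s']:.3g} | "
                             f"{r.papp_corrected:.3g} | {err:+.1%} |")
        lines.append("")

    if expression is not None:
        lines += ["## Relative expression (dCt to housekeeping)", ""]
        lines += ["```", expression.to_string(index=False, float_format="%.3f"), "```", ""]

    with open(path, "w") as fh:
        fh.write("\n".join(lines))
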