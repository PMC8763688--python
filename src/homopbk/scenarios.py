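"""Config-driven scenario runner for the packaged exposure workflows.

Scenarios are YAML documents (packaged under ``homopbk/data``) describing a
species, substance set, dosing design and optional population/uncertainty
block. :func:`run_scenario` executes build → simulate → metrics
(→ population when configured) and writes the plasma curve, a metrics
summary and — for population runs — a per-individual table, every file
stamped with the configuration hash. Each model build emits one structured
log line per parameter group so a reviewer can audit the values used.

This module is a library surface (no shell entry point): call
:func:`list_scenarios` / :func:`run_scenario` from Python, or see the
examples directory.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .metrics import accumulation_ratio, compute_metrics
from .pbk import (DoseRegimen, calibrate_oral_absorption, dose_per_area,
                  simulate)
from .population import (PopulationSpec, UncertainParameter,
                         generate_population, population_simulate,
                         sample_uncertain_parameters)
from .presets import (human_dermal_model, rat_reference_model)
from .substance import packaged_substance
from .synthetic import MUST_APPLICATION_TIMES

log = logging.getLogger(__name__)

_ROUTES = ("iv_bolus", "oral", "dermal", "dermal_clinical")


@dataclass
class ScenarioConfig:
    """Validated scenario description."""

    scenario_id: str
    description: str
    species: str
    route: str
    substance: str = "homosalate_optimized"
    doses_mg_kg: list[float] = field(default_factory=list)
    n_days: int = 1
    t_end_h: float | None = None
    window: tuple[float, float] | None = None
    fb_target: float | None = None
    # dermal fields
    fractions: list[float] = field(default_factory=list)
    daily_dose_ug_cm2: float | None = None
    area_cm2: float | None = None
    doses_per_day: int = 2
    product_fraction: float = 0.10
    application_times: list[float] | None = None
    # population
    population_n: int | None = None
    population_seed: int = 0
    uncertainty: dict | None = None

    def __post_init__(self) -> None:
        if self.route not in _ROUTES:
            raise ValidationError(f"unknown route {self.route!r}")
        if self.route in ("iv_bolus", "oral") and not self.doses_mg_kg:
            raise ValidationError(f"{self.scenario_id}: doses_mg_kg required")
        if self.route.startswith("dermal") and not (self.fractions
                                                    and self.area_cm2):
            raise ValidationError(
                f"{self.scenario_id}: dermal scenarios need fractions and area")

    def config_hash(self) -> str:
        canon = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _packaged_configs() -> dict[str, dict]:
    out = {}
    for ref in resources.files("homopbk.data").iterdir():
        if ref.name.endswith(".yaml") and ref.name.startswith("scenario_"):
            doc = yaml.safe_load(ref.read_text())
            out[doc["scenario_id"]] = doc
    return out


def list_scenarios() -> dict[str, str]:
    """Packaged scenario ids mapped to their descriptions."""
    return {k: v.get("description", "") for k, v in
            sorted(_packaged_configs().items())}


def load_scenario(scenario_id: str) -> ScenarioConfig:
    configs = _packaged_configs()
    if scenario_id not in configs:
        near = difflib.get_close_matches(scenario_id, configs.keys(), n=1)
        hint = f"; nearest match: {near[0]!r}" if near else ""
        raise ValidationError(f"unknown scenario {scenario_id!r}{hint}")
    doc = dict(configs[scenario_id])
    if doc.get("window") is not None:
        doc["window"] = tuple(doc["window"])
    return ScenarioConfig(**doc)


def _log_model_parameters(model, scenario_id: str) -> None:
    s, c = model.substance, model.clearance_spec
    log.info("scenario=%s substance name=%s MW=%g logP=%g pKa=%g Fu=%g "
             "K_bc:pl=%g P_endo=%g P_cell=%g", scenario_id, s.name,
             s.molecular_weight, s.log_p, s.pka, s.fraction_unbound,
             s.blood_cell_plasma_partition, s.endothelial_permeability,
             s.cellular_permeability)
    log.info("scenario=%s clearance mode=%s CLs=%s CLint=%s CLrenal=%g",
             scenario_id, c.mode, c.total_plasma_clearance,
             c.intrinsic_clearance, c.renal_clearance)
    log.info("scenario=%s individual species=%s BW=%g kg CO=%g L/h hct=%g",
             scenario_id, model.individual.species,
             model.individual.body_weight, model.individual.cardiac_output,
             model.individual.hematocrit)


def _write(out_dir: Path, name: str, payload: dict, cfg_hash: str) -> None:
    payload = {"config_hash": cfg_hash, **payload}
    (out_dir / name).write_text(json.dumps(payload, indent=2, default=str))


def _metrics_dict(m) -> dict:
    return {"cmax_ng_ml": m.cmax, "tmax_h": m.tmax,
            "auc_0_24_ng_h_ml": m.auc_0_24, "auc_inf_ng_h_ml": m.auc_inf}


def run_scenario(
    config: ScenarioConfig | str,
    out_dir: str | Path,
    seed: int = 0,
    overrides: dict | None = None,
) -> dict:
    """Execute a scenario end-to-end; returns and writes the summary.

    ``overrides`` may shrink the work for quick runs: keys ``fractions``,
    ``doses_mg_kg``, ``population_n``, ``n_days``.
    """
    if isinstance(config, str):
        config = load_scenario(config)
    for key, value in (overrides or {}).items():
        if not hasattr(config, key):
            raise ValidationError(f"unknown override {key!r}")
        setattr(config, key, value)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    substance = packaged_substance(config.substance)
    summary: dict = {"scenario_id": config.scenario_id, "seed": seed}

    if config.route == "iv_bolus":
        model = rat_reference_model(substance=substance)
        _log_model_parameters(model, config.scenario_id)
        t_end = config.t_end_h or 24.0
        per_dose = {}
        for dose in config.doses_mg_kg:
            res = simulate(model, DoseRegimen(route="iv_bolus", dose=dose),
                           t_end=t_end)
            m = compute_metrics(res, window=config.window or (0.0, t_end))
            per_dose[dose] = _metrics_dict(m)
            res.to_frame().to_csv(out_dir / f"curve_iv_{dose}.csv", index=False)
        summary["per_dose"] = per_dose

    elif config.route == "oral":
        model = rat_reference_model(substance=substance, with_oral=True)
        _log_model_parameters(model, config.scenario_id)
        regimen0 = DoseRegimen(route="oral", dose=config.doses_mg_kg[0],
                               n_days=config.n_days)
        if config.fb_target is not None:
            spec = calibrate_oral_absorption(model, regimen0, config.fb_target)
            log.info("scenario=%s oral calibration P_int=%g cm/min Fa=%.3f",
                     config.scenario_id, spec.intestinal_permeability,
                     spec.fraction_absorbed)
            model = rat_reference_model(substance=substance, with_oral=True,
                                        oral_spec=spec)
            summary["oral_absorption"] = {
                "intestinal_permeability_cm_min": spec.intestinal_permeability,
                "fraction_absorbed": spec.fraction_absorbed,
                "fb_target": config.fb_target,
            }
        t_end = 24.0 * config.n_days
        window = config.window or (t_end - 24.0, t_end)
        per_dose = {}
        for dose in config.doses_mg_kg:
            res = simulate(model, DoseRegimen(route="oral", dose=dose,
                                              n_days=config.n_days),
                           t_end=t_end, points_per_interval=60)
            m = compute_metrics(res, window=window)
            per_dose[dose] = _metrics_dict(m)
        summary["per_dose"] = per_dose

    elif config.route == "dermal":
        daily = config.daily_dose_ug_cm2 or dose_per_area(
            18.0, config.product_fraction, config.area_cm2)
        t_end = config.t_end_h or 24.0 * config.n_days
        window = config.window or (t_end - 24.0, t_end)
        per_fraction = {}
        for fraction in config.fractions:
            model = human_dermal_model(fraction=fraction, applied_dose=daily,
                                       area=config.area_cm2)
            _log_model_parameters(model, config.scenario_id)
            regimen = DoseRegimen(route="dermal", dose=daily,
                                  n_days=config.n_days,
                                  doses_per_day=config.doses_per_day,
                                  application_area=config.area_cm2,
                                  product_fraction=config.product_fraction)
            entry: dict = {}
            if config.population_n:
                entry.update(_dermal_population(config, fraction, daily,
                                                regimen, t_end, window, seed))
            res = simulate(model, regimen, t_end=t_end)
            m = compute_metrics(res, window=window)
            entry["reference_individual"] = _metrics_dict(m)
            if config.n_days > 1:
                entry["accumulation_ratio"] = accumulation_ratio(res)
            per_fraction[fraction] = entry
        summary["daily_dose_ug_cm2"] = daily
        summary["per_fraction"] = per_fraction

    else:  # dermal_clinical
        fraction = config.fractions[0]
        dose = config.daily_dose_ug_cm2 or 150.0
        model = human_dermal_model(fraction=fraction, applied_dose=dose,
                                   area=config.area_cm2)
        _log_model_parameters(model, config.scenario_id)
        times = tuple(config.application_times or MUST_APPLICATION_TIMES)
        regimen = DoseRegimen(route="dermal", dose=dose, times=times,
                              application_area=config.area_cm2,
                              product_fraction=config.product_fraction)
        t_end = config.t_end_h or (max(times) + 24.0)
        res = simulate(model, regimen, t_end=t_end)
        m = compute_metrics(res, window=config.window or (0.0, 24.0))
        res.to_frame().to_csv(out_dir / "curve_clinical.csv", index=False)
        summary["metrics"] = _metrics_dict(m)
        summary["fraction"] = fraction

    _write(out_dir, f"{config.scenario_id}_summary.json", summary, cfg_hash)
    return summary


def _dermal_population(config: ScenarioConfig, fraction: float, daily: float,
                       regimen: DoseRegimen, t_end: float,
                       window: tuple[float, float], seed: int) -> dict:
    pop_spec = PopulationSpec(species=config.species,
                              n_individuals=config.population_n,
                              seed=config.population_seed + seed)
    population = generate_population(pop_spec)
    draws = None
    if config.uncertainty:
        uspec = {name: UncertainParameter(**params)
                 for name, params in config.uncertainty.items()}
        draws = sample_uncertain_parameters(uspec, len(population),
                                            seed=pop_spec.seed + 1)

    def build(individual, draw_row):
        substance = packaged_substance(config.substance)
        sub_over = {k: v for k, v in draw_row.items()
                    if hasattr(substance, k)}
        if sub_over:
            substance = substance.replace(**sub_over)
        clint = draw_row.get("intrinsic_clearance",
                             None)
        kwargs = {} if clint is None else {"intrinsic_clearance": float(clint)}
        return human_dermal_model(fraction=fraction, applied_dose=daily,
                                  area=config.area_cm2, substance=substance,
                                  individual=individual, **kwargs)

    pop_res = population_simulate(build, regimen, population,
                                  parameter_draws=draws, t_end=t_end,
                                  window=window, seed=pop_spec.seed)
    return {"population": pop_res.summary_json_dict()}
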