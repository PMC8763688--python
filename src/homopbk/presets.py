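"""Ready-made model configurations for the packaged homosalate workflows.

These assemble the pieces the way the study design uses them:

* rat model with the optimized substance set and total plasma clearance
  6 L/h/kg from the legacy IV study;
* human model with IVIVE hepatic clearance from in vitro hepatocyte
  intrinsic clearance (59.6 µL/min/10⁶ cells) and renal clearance zero;
* human dermal model whose skin grid is calibrated to a target 24-h
  penetrated fraction of the applied dose (2 / 2.5 / 3.86 / 5.3% scenarios).

Calibrated skin grids are cached per (fraction, dose) because they do not
depend on the individual.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

from .dermal import SkinGrid, build_skin_grid, calibrate_to_fraction
from .distribution import build_partition_set
from .pbk import (ClearanceSpec, OralAbsorptionSpec, PBKModel, build_model,
                  couple_to_systemic, default_oral_spec)
from .physiology import Individual, build_individual
from .substance import SubstanceProperties, packaged_substance

#: total plasma clearance measured in the legacy rat IV study, L/h/kg
RAT_TOTAL_PLASMA_CLEARANCE = 6.0
#: in vitro intrinsic clearance in primary human hepatocytes, µL/min/10⁶ cells
HUMAN_INTRINSIC_CLEARANCE = 59.6

_grid_cache: dict[tuple[float, float], SkinGrid] = {}


def rat_clearance_spec() -> ClearanceSpec:
    return ClearanceSpec(mode="total_plasma",
                         total_plasma_clearance=RAT_TOTAL_PLASMA_CLEARANCE)


def human_clearance_spec(intrinsic_clearance: float = HUMAN_INTRINSIC_CLEARANCE
                         ) -> ClearanceSpec:
    return ClearanceSpec(mode="hepatic_ivive",
                         intrinsic_clearance=intrinsic_clearance,
                         renal_clearance=0.0)


def rat_reference_model(
    substance: SubstanceProperties | None = None,
    individual: Individual | None = None,
    with_oral: bool = False,
    oral_spec: OralAbsorptionSpec | None = None,
) -> PBKModel:
    """Rat whole-body model with the identified substance parameter set."""
    substance = substance or packaged_substance("homosalate_optimized")
    individual = individual or build_individual("rat")
    pset = build_partition_set(substance, individual)
    if with_oral and oral_spec is None:
        oral_spec = default_oral_spec("rat")
    return build_model(individual, substance, pset, rat_clearance_spec(),
                       oral_spec=oral_spec)


def human_reference_model(
    substance: SubstanceProperties | None = None,
    individual: Individual | None = None,
    intrinsic_clearance: float = HUMAN_INTRINSIC_CLEARANCE,
) -> PBKModel:
    """Human whole-body model with IVIVE hepatic clearance, renal CL = 0."""
    substance = substance or packaged_substance("homosalate_optimized")
    individual = individual or build_individual("human")
    pset = build_partition_set(substance, individual)
    return build_model(individual, substance, pset,
                       human_clearance_spec(intrinsic_clearance))


def calibrated_skin_grid(fraction: float, applied_dose: float) -> SkinGrid:
    """Skin grid calibrated so Q(24 h)/dose equals ``fraction`` (cached)."""
    key = (round(fraction, 10), round(applied_dose, 6))
    grid = _grid_cache.get(key)
    if grid is None:
        grid = calibrate_to_fraction(build_skin_grid(), applied_dose, fraction)
        _grid_cache[key] = grid
    return grid


def human_dermal_model(
    fraction: float,
    applied_dose: float,
    area: float,
    substance: SubstanceProperties | None = None,
    individual: Individual | None = None,
    intrinsic_clearance: float = HUMAN_INTRINSIC_CLEARANCE,
) -> PBKModel:
    """Human model coupled to a skin grid calibrated for the scenario.

    ``applied_dose`` is the daily substance load per skin area (µg/cm²)
    used for the calibration target; ``area`` the application area (cm²).
    """
    base = human_reference_model(substance=substance, individual=individual,
                                 intrinsic_clearance=intrinsic_clearance)
    grid = calibrated_skin_grid(fraction, applied_dose)
    return couple_to_systemic(base, grid, area)
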