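"""Whole-body compartmental kinetic model: assembly, dosing and integration.

Each perfused organ contributes four sub-compartments — vascular plasma,
vascular blood cells, interstitial space and intracellular space — linked by

* blood-flow-limited convection between the arterial pool, the organ
  vascular space and the venous pool (the lung sits in series between the
  venous and arterial pools and carries the whole cardiac output; splanchnic
  organs drain into the liver inflow, giving a mechanistic hepatic
  first pass for orally absorbed drug),
* endothelial-permeability-limited exchange between vascular plasma and
  interstitium, driven by unbound concentrations,
* cellular-permeability-limited exchange between interstitium and cells,
  with the unbound tissue:plasma-water partition coefficient (Kpu) as the
  equilibrium ratio,
* directional plasma <-> blood-cell exchange with the blood-cell:plasma
  coefficient as equilibrium ratio.

Elimination is either total plasma clearance applied to venous plasma
(rat mode, clearance taken from an in vivo study) or whole-liver intrinsic
clearance acting on the unbound intracellular liver concentration (human
mode, scaled from in vitro hepatocyte data by IVIVE); renal clearance is a
separate first-order term on kidney plasma, zero by default.

All processes are linear, so the system is assembled once as a constant
rate matrix; integration uses a stiff BDF solver with the exact Jacobian,
restarted at bolus/application events. Organs with zero blood flow
(gallbladder, saliva in the human table) are inert volume pools and are
excluded from the state.

Internal units: amounts µg, volumes mL, time h, flows mL/h,
concentrations µg/mL internally, reported plasma concentration ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import brentq

from .dermal import SkinGrid
from .distribution import PartitionSet, effective_permeability
from .errors import (CalibrationError, ConstructionError, RangeError,
                     SimulationError, ValidationError)
from .physiology import Individual
from .substance import SubstanceProperties
from .units import MIN_PER_H, ML_PER_L, NG_PER_UG, UG_PER_MG

#: default hepatocellularity, million cells per g liver (documented constant)
DEFAULT_HEPATOCELLULARITY = 120.0


@dataclass(frozen=True)
class ClearanceSpec:
    """Elimination configuration; exactly one mode is active.

    ``total_plasma`` applies ``total_plasma_clearance`` (L/h/kg) to venous
    plasma. ``hepatic_ivive`` scales ``intrinsic_clearance``
    (µL/min/10⁶ cells) to the whole liver via hepatocellularity and liver
    mass and applies it to unbound intracellular liver drug. Renal clearance
    (L/h, on kidney plasma) defaults to zero.
    """

    mode: str
    total_plasma_clearance: float | None = None    # L/h/kg
    intrinsic_clearance: float | None = None       # µL/min/10⁶ cells
    hepatocellularity: float = DEFAULT_HEPATOCELLULARITY  # 10⁶ cells/g
    renal_clearance: float = 0.0                   # L/h

    def __post_init__(self) -> None:
        if self.mode not in ("total_plasma", "hepatic_ivive"):
            raise ValidationError(f"unknown clearance mode {self.mode!r}")
        if self.mode == "total_plasma" and self.total_plasma_clearance is None:
            raise ValidationError("total_plasma mode requires total_plasma_clearance")
        if self.mode == "hepatic_ivive" and self.intrinsic_clearance is None:
            raise ValidationError("hepatic_ivive mode requires intrinsic_clearance")
        for name in ("total_plasma_clearance", "intrinsic_clearance",
                     "renal_clearance", "hepatocellularity"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RangeError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class OralAbsorptionSpec:
    """First-order gut absorption derived from an intestinal permeability.

    The gut lumen is a single well-mixed compartment. Absorption competes
    with luminal transit (fecal loss), so the fraction absorbed is
    Fa = ka/(ka + k_transit) with ka = permeability × effective surface
    area / lumen volume.
    """

    intestinal_permeability: float      # cm/min
    lumen_volume: float                 # mL
    effective_surface_area: float       # cm²
    transit_rate: float                 # 1/h
    fraction_absorbed_target: float | None = None
    bioavailability_target: float | None = None

    def __post_init__(self) -> None:
        for name in ("intestinal_permeability", "lumen_volume",
                     "effective_surface_area", "transit_rate"):
            if getattr(self, name) < 0:
                raise RangeError(f"{name} must be >= 0")
        fa, fb = self.fraction_absorbed_target, self.bioavailability_target
        if fa is not None and not (0.0 <= fa <= 1.0):
            raise RangeError("fraction_absorbed_target must be in [0, 1]")
        if fb is not None and fa is not None and fb > fa:
            raise ValidationError("bioavailability target cannot exceed Fa target")

    @property
    def absorption_rate(self) -> float:
        """ka, 1/h."""
        p_cm_h = self.intestinal_permeability * MIN_PER_H
        return p_cm_h * self.effective_surface_area / self.lumen_volume

    @property
    def fraction_absorbed(self) -> float:
        ka = self.absorption_rate
        if ka == 0.0 and self.transit_rate == 0.0:
            return 0.0
        return ka / (ka + self.transit_rate)


def default_oral_spec(species: str = "rat") -> OralAbsorptionSpec:
    """Packaged defaults: lumen geometry and transit per species."""
    if species == "rat":
        return OralAbsorptionSpec(
            intestinal_permeability=0.01, lumen_volume=4.0,
            effective_surface_area=100.0, transit_rate=0.66,
        )
    return OralAbsorptionSpec(
        intestinal_permeability=0.01, lumen_volume=250.0,
        effective_surface_area=7000.0, transit_rate=0.35,
    )


@dataclass(frozen=True)
class DoseRegimen:
    """Dosing schedule for a simulation.

    ``dose`` is mg/kg per administration for iv_bolus/oral. For dermal
    dosing on the ``n_days``/``doses_per_day`` grid, ``dose`` is the daily
    µg/cm² split evenly across the day's applications; with explicit
    ``times`` (h) it is the µg/cm² per application.
    """

    route: str
    dose: float
    times: tuple[float, ...] | None = None
    n_days: int = 1
    doses_per_day: int = 1
    application_area: float | None = None   # cm², dermal
    product_fraction: float | None = None   # e.g. 0.10 for a 10% product

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "oral", "dermal"):
            raise ValidationError(f"unknown route {self.route!r}")
        if self.dose <= 0:
            raise RangeError("dose must be > 0")
        if self.times is not None and list(self.times) != sorted(self.times):
            raise ValidationError("times must be sorted ascending")
        if self.route == "dermal" and (self.application_area is None
                                       or self.product_fraction is None):
            raise ValidationError("dermal route requires application_area "
                                  "and product_fraction")

    def event_times(self) -> np.ndarray:
        if self.times is not None:
            return np.asarray(self.times, dtype=float)
        interval = 24.0 / self.doses_per_day
        return np.array([
            24.0 * day + k * interval
            for day in range(self.n_days)
            for k in range(self.doses_per_day)
        ])

    def dose_per_event_ug(self, body_weight_kg: float) -> float:
        """Systemic routes: µg per administration."""
        return self.dose * body_weight_kg * UG_PER_MG

    def dermal_dose_per_event_ug_cm2(self) -> float:
        if self.times is not None:
            return self.dose
        return self.dose / self.doses_per_day


def dose_per_area(product_grams_per_day: float, product_fraction: float,
                  area_cm2: float) -> float:
    """Daily substance dose per skin area, µg/cm²/day.

    E.g. 18 g/day of a 10% product over 17500 cm² → ≈103 µg/cm²/day.
    """
    if area_cm2 <= 0:
        raise RangeError("area must be > 0")
    return product_grams_per_day * 1.0e6 * product_fraction / area_cm2


@dataclass
class SimulationResult:
    """Integrated time course with per-compartment amounts and mass audit."""

    time: np.ndarray                       # h
    plasma_concentration: np.ndarray       # ng/mL, venous plasma
    amounts: dict[str, np.ndarray]         # µg per labelled compartment
    cumulative_eliminated: np.ndarray      # µg (metabolic + renal + fecal)
    cumulative_absorbed: np.ndarray        # µg entered systemic circulation
    dose_administered: float               # µg placed into the system, total
    cumulative_administered: np.ndarray | None = None   # µg, running total
    metadata: dict = field(default_factory=dict)

    def total_in_system(self) -> np.ndarray:
        return sum(self.amounts.values())

    def mass_balance_error(self) -> float:
        """Max relative deviation of (in-system + eliminated) from the dose
        administered up to each output time."""
        if self.dose_administered == 0:
            return 0.0
        given = (self.cumulative_administered
                 if self.cumulative_administered is not None
                 else self.dose_administered)
        recovered = self.total_in_system() + self.cumulative_eliminated
        return float(np.max(np.abs(recovered - given))
                     / self.dose_administered)

    def to_frame(self) -> pd.DataFrame:
        frames = [pd.DataFrame({
            "time_h": self.time, "compartment": label, "amount_ug": series,
        }) for label, series in self.amounts.items()]
        tidy = pd.concat(frames, ignore_index=True)
        plasma = pd.DataFrame({
            "time_h": self.time, "compartment": "venous_plasma_conc",
            "plasma_ng_per_ml": self.plasma_concentration,
        })
        return pd.concat([tidy, plasma], ignore_index=True)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PBKModel:
    """Assembled whole-body model: rate matrix plus compartment index map."""

    individual: Individual
    substance: SubstanceProperties
    partition_set: PartitionSet
    clearance_spec: ClearanceSpec
    oral_spec: OralAbsorptionSpec | None
    index: dict[str, int]
    matrix: np.ndarray
    n_dynamic: int              # states before cumulative trackers
    skin_grid: SkinGrid | None = None
    application_area: float | None = None
    options: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @property
    def venous_plasma_volume(self) -> float:
        return self.individual.venous_blood_volume * (1.0 - self.individual.hematocrit)


def build_model(
    individual: Individual,
    substance: SubstanceProperties,
    partition_set: PartitionSet,
    clearance_spec: ClearanceSpec,
    oral_spec: OralAbsorptionSpec | None = None,
    options: dict | None = None,
) -> PBKModel:
    """Assemble the constant rate matrix of the whole-body ODE system.

    ``options`` may override the specific exchange surface areas
    (``sa_endothelial``, ``sa_cellular``, ``sa_blood_cell``, cm²/mL of
    tissue or blood-cell volume).
    """
    opts = {"sa_endothelial": 1.0, "sa_cellular": 1.0, "sa_blood_cell": 1.0}
    opts.update(options or {})

    organs = [o for o in individual.organs if o.blood_flow > 0]
    missing = [o.name for o in organs if o.name not in partition_set.kpu]
    if missing:
        raise ConstructionError(f"partition set lacks organs {missing}")
    if not any(o.name == "lung" for o in organs):
        raise ConstructionError("organ table must include a perfused lung")
    if not any(o.name == "liver" for o in organs):
        raise ConstructionError("organ table must include a perfused liver")

    hct = individual.hematocrit
    ph = individual.plasma_ph
    fu = substance.fraction_unbound
    p_endo = effective_permeability(
        substance.endothelial_permeability, substance, ph) * MIN_PER_H
    p_cell = effective_permeability(
        substance.cellular_permeability, substance, ph) * MIN_PER_H
    p_pl2bc = effective_permeability(
        substance.plasma_to_blood_cell_permeability, substance, ph) * MIN_PER_H
    p_bc2pl = effective_permeability(
        substance.blood_cell_to_plasma_permeability, substance, ph) * MIN_PER_H
    k_bcpl = substance.blood_cell_plasma_partition

    index: dict[str, int] = {}

    def add(label: str) -> int:
        index[label] = len(index)
        return index[label]

    for o in organs:
        for sub in ("pl", "bc", "int", "cell"):
            add(f"{o.name}.{sub}")
    add("arterial.pl"); add("arterial.bc")
    add("venous.pl"); add("venous.bc")
    if oral_spec is not None:
        add("gut_lumen")
    n_dynamic = len(index)
    i_elim = add("cum_eliminated")
    i_abs = add("cum_absorbed")

    n = len(index)
    a = np.zeros((n, n))

    vol = {}
    for o in organs:
        v_vasc = o.volume * o.vascular_fraction
        vol[f"{o.name}.pl"] = v_vasc * (1.0 - hct)
        vol[f"{o.name}.bc"] = v_vasc * hct
        vol[f"{o.name}.int"] = o.volume * o.interstitial_fraction
        vol[f"{o.name}.cell"] = o.volume * o.cellular_fraction
    vol["arterial.pl"] = individual.arterial_blood_volume * (1.0 - hct)
    vol["arterial.bc"] = individual.arterial_blood_volume * hct
    vol["venous.pl"] = individual.venous_blood_volume * (1.0 - hct)
    vol["venous.bc"] = individual.venous_blood_volume * hct

    def conc_coeff(label: str) -> float:
        return 1.0 / vol[label]

    def flow_link(src: str, dst: str, q_ml_h: float) -> None:
        """Convective transfer q·C_src from src to dst."""
        c = q_ml_h * conc_coeff(src)
        a[index[src], index[src]] -= c
        a[index[dst], index[src]] += c

    co_pl = individual.cardiac_output * ML_PER_L * (1.0 - hct)
    co_bc = individual.cardiac_output * ML_PER_L * hct

    lung = next(o for o in organs if o.name == "lung")
    systemic = [o for o in organs if o.name != "lung"]
    portal = [o for o in systemic if o.portal]
    liver = next(o for o in systemic if o.name == "liver")

    # venous -> lung -> arterial (full cardiac output in series)
    flow_link("venous.pl", "lung.pl", co_pl)
    flow_link("venous.bc", "lung.bc", co_bc)
    flow_link("lung.pl", "arterial.pl", co_pl)
    flow_link("lung.bc", "arterial.bc", co_bc)

    for o in systemic:
        q_pl = o.blood_flow * ML_PER_L * (1.0 - hct)
        q_bc = o.blood_flow * ML_PER_L * hct
        flow_link("arterial.pl", f"{o.name}.pl", q_pl)
        flow_link("arterial.bc", f"{o.name}.bc", q_bc)
        if o.portal:
            flow_link(f"{o.name}.pl", "liver.pl", q_pl)
            flow_link(f"{o.name}.bc", "liver.bc", q_bc)
        elif o.name != "liver":
            flow_link(f"{o.name}.pl", "venous.pl", q_pl)
            flow_link(f"{o.name}.bc", "venous.bc", q_bc)
    # liver drains its arterial inflow plus the portal inflows
    q_liver_total = (liver.blood_flow + sum(o.blood_flow for o in portal)) * ML_PER_L
    flow_link("liver.pl", "venous.pl", q_liver_total * (1.0 - hct))
    flow_link("liver.bc", "venous.bc", q_liver_total * hct)

    def exchange(src: str, dst: str, ps_fwd: float, ps_back: float) -> None:
        """Bidirectional permeability exchange with possibly unequal PS."""
        cf = ps_fwd * conc_coeff(src)
        cb = ps_back * conc_coeff(dst)
        a[index[src], index[src]] -= cf
        a[index[dst], index[src]] += cf
        a[index[dst], index[dst]] -= cb
        a[index[src], index[dst]] += cb

    # plasma <-> blood cells in every vascular space
    bc_spaces = [(f"{o.name}.pl", f"{o.name}.bc", vol[f"{o.name}.bc"]) for o in organs]
    bc_spaces += [("arterial.pl", "arterial.bc", vol["arterial.bc"]),
                  ("venous.pl", "venous.bc", vol["venous.bc"])]
    for pl_label, bc_label, v_bc in bc_spaces:
        sa = opts["sa_blood_cell"] * v_bc
        exchange(pl_label, bc_label, sa * p_pl2bc, sa * p_bc2pl / k_bcpl)

    # plasma <-> interstitial <-> intracellular per organ
    for o in organs:
        sa_t = opts["sa_endothelial"] * o.volume
        exchange(f"{o.name}.pl", f"{o.name}.int", sa_t * p_endo * fu, sa_t * p_endo * fu)
        sa_c = opts["sa_cellular"] * o.volume
        kpu = partition_set.kpu[o.name]
        exchange(f"{o.name}.int", f"{o.name}.cell",
                 sa_c * p_cell * fu, sa_c * p_cell / kpu)

    # elimination
    if clearance_spec.mode == "total_plasma":
        cl = clearance_spec.total_plasma_clearance * individual.body_weight * ML_PER_L
        c = cl * conc_coeff("venous.pl")
        a[index["venous.pl"], index["venous.pl"]] -= c
        a[i_elim, index["venous.pl"]] += c
    else:
        liver_mass_g = liver.volume  # density ~1 g/mL
        clint_whole_ml_h = (clearance_spec.intrinsic_clearance
                            * clearance_spec.hepatocellularity
                            * liver_mass_g * MIN_PER_H / 1000.0)
        kpu_liver = partition_set.kpu["liver"]
        c = clint_whole_ml_h / kpu_liver * conc_coeff("liver.cell")
        a[index["liver.cell"], index["liver.cell"]] -= c
        a[i_elim, index["liver.cell"]] += c
    if clearance_spec.renal_clearance > 0:
        clr = clearance_spec.renal_clearance * ML_PER_L
        c = clr * conc_coeff("kidney.pl")
        a[index["kidney.pl"], index["kidney.pl"]] -= c
        a[i_elim, index["kidney.pl"]] += c

    # oral absorption: lumen -> gut vascular plasma (then portal -> liver),
    # in competition with luminal transit (fecal loss -> eliminated)
    if oral_spec is not None:
        ka = oral_spec.absorption_rate
        ktr = oral_spec.transit_rate
        il = index["gut_lumen"]
        a[il, il] -= ka + ktr
        a[index["gut.pl"], il] += ka
        a[i_abs, il] += ka
        a[i_elim, il] += ktr  # fecal loss counted as eliminated

    return PBKModel(
        individual=individual, substance=substance,
        partition_set=partition_set, clearance_spec=clearance_spec,
        oral_spec=oral_spec, index=index, matrix=a, n_dynamic=n_dynamic,
        options=opts,
    )


def couple_to_systemic(model: PBKModel, grid: SkinGrid, area: float) -> PBKModel:
    """Attach a skin grid: node uptake feeds venous plasma, scaled by area.

    Skin states stay in µg/cm²; the transfer into the body multiplies by the
    application area. Dermal dose events load the vehicle compartment.
    """
    if model.skin_grid is not None:
        raise ConstructionError("model already has a dermal route")
    # plausible whole-body surface bound (cm²): ~3 m² human, 0.1 m² rat
    bsa_limit = 30000.0 if model.individual.species == "human" else 1000.0
    if area > bsa_limit:
        raise ValidationError(
            f"application area {area} cm² exceeds plausible body surface "
            f"({bsa_limit:.0f} cm²)")

    old_n = model.n_states
    ns = grid.n_states
    index = dict(model.index)
    base = old_n
    index["skin_vehicle"] = base
    for j in range(grid.n_nodes):
        index[f"skin_node_{j}"] = base + 1 + j
    index["skin_surface_pool"] = base + grid.n_nodes + 1

    n = old_n + ns
    a = np.zeros((n, n))
    a[:old_n, :old_n] = model.matrix
    a[base:base + ns, base:base + ns] = grid.matrix
    i_ven = model.index["venous.pl"]
    i_elim = model.index["cum_eliminated"]
    i_abs = model.index["cum_absorbed"]
    # penetrated flux (µg/cm²/h per state) into venous plasma, scaled by area
    pen = grid.penetration_row
    a[i_ven, base:base + ns] += area * pen
    a[i_abs, base:base + ns] += area * pen
    # cumulative trackers stay trailing conceptually; dynamic block now
    # includes skin states appended after them — record explicitly
    return PBKModel(
        individual=model.individual, substance=model.substance,
        partition_set=model.partition_set, clearance_spec=model.clearance_spec,
        oral_spec=model.oral_spec, index=index, matrix=a,
        n_dynamic=model.n_dynamic, skin_grid=grid, application_area=area,
        options=dict(model.options),
    )


def _interval_grid(points: int) -> np.ndarray:
    """Normalized output grid on [0, 1] for one inter-dose interval.

    Mixes geometric spacing near 0 (resolving the fast disposition right
    after a bolus, which a uniform grid would integrate poorly) with a
    uniform tail; returned sorted, unique, spanning exactly [0, 1].
    """
    n_geo = max(4, points // 2)
    n_lin = max(4, points - n_geo)
    geo = np.geomspace(1.0e-5, 1.0, n_geo)
    lin = np.linspace(0.0, 1.0, n_lin + 1)
    return np.unique(np.concatenate(([0.0], geo, lin)))


def _dynamic_indices(model: PBKModel) -> np.ndarray:
    """Indices of mass-carrying, non-cumulative states."""
    skip = {model.index["cum_eliminated"], model.index["cum_absorbed"]}
    return np.array([i for i in range(model.n_states) if i not in skip])


def simulate(
    model: PBKModel,
    regimen: DoseRegimen,
    t_end: float,
    rtol: float = 1.0e-6,
    atol: float = 1.0e-9,
    points_per_interval: int = 60,
    method: str = "expm",
) -> SimulationResult:
    """Integrate the model under a dosing regimen.

    Bolus/application events restart the integrator; the output grid places
    ``points_per_interval`` points in each inter-dose interval (well above
    the 20-point floor needed to resolve C_max).

    The default ``method='expm'`` exploits that the system is linear and
    time-invariant between events: states advance by the matrix exponential
    of the rate matrix over each output sub-step, which is exact (to
    floating point), unconditionally stable and preserves non-negativity.
    ``method='bdf'`` uses the stiff ODE solver with the exact Jacobian and
    the stated tolerances instead.
    """
    if method not in ("expm", "bdf"):
        raise ValidationError(f"method must be 'expm' or 'bdf', got {method!r}")
    if regimen.route == "dermal" and model.skin_grid is None:
        raise ConstructionError("dermal regimen requires a skin-coupled model "
                                "(couple_to_systemic)")
    if regimen.route == "oral" and model.oral_spec is None:
        raise ConstructionError("oral regimen requires an oral absorption spec")

    events = [t for t in regimen.event_times() if t < t_end]
    if not events:
        raise ValidationError("no dose events before t_end")
    bw = model.individual.body_weight
    if regimen.route == "iv_bolus":
        target = model.index["venous.pl"]
        amount = regimen.dose_per_event_ug(bw)
    elif regimen.route == "oral":
        target = model.index["gut_lumen"]
        amount = regimen.dose_per_event_ug(bw)
    else:
        target = model.index["skin_vehicle"]
        amount = regimen.dermal_dose_per_event_ug_cm2()

    a = model.matrix

    def rhs(t, x):
        return a @ x

    def jac(t, x):
        return a

    boundaries = list(events) + [t_end]
    x = np.zeros(model.n_states)
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    given: list[np.ndarray] = []
    administered = 0.0
    i_abs = model.index["cum_absorbed"]
    propagators: dict[float, np.ndarray] = {}

    for k, t0 in enumerate(boundaries[:-1]):
        # every segment start is a dose event by construction
        x = x.copy()
        x[target] += amount
        if regimen.route == "iv_bolus":
            x[i_abs] += amount  # IV enters systemic directly
        if regimen.route == "dermal":
            administered += amount * (model.application_area or 1.0)
        else:
            administered += amount
        t1 = boundaries[k + 1]
        if t1 <= t0:
            continue
        t_eval = t0 + (t1 - t0) * _interval_grid(points_per_interval)
        if method == "expm":
            steps = np.round(np.diff(t_eval), 12)
            seg = np.empty((model.n_states, len(t_eval)))
            seg[:, 0] = x
            for j, dt in enumerate(steps):
                prop = propagators.get(dt)
                if prop is None:
                    prop = expm(a * dt)
                    propagators[dt] = prop
                seg[:, j + 1] = prop @ seg[:, j]
            seg_t = t_eval
            x = seg[:, -1]
        else:
            sol = solve_ivp(rhs, (t0, t1), x, method="BDF", jac=jac,
                            t_eval=t_eval, rtol=rtol, atol=atol)
            if not sol.success:
                raise SimulationError(
                    f"solver failed in interval [{t0}, {t1}]: {sol.message}",
                    last_time=float(sol.t[-1]) if len(sol.t) else t0,
                )
            seg, seg_t = sol.y, sol.t
            x = seg[:, -1]
        # drop the duplicated segment-start point except for the first segment
        s = 0 if k == 0 else 1
        times.append(seg_t[s:])
        states.append(seg[:, s:])
        given.append(np.full(len(seg_t) - s, administered))

    t = np.concatenate(times)
    y = np.concatenate(states, axis=1)
    administered_t = np.concatenate(given)
    # clip solver noise: amounts are physically non-negative
    dyn = _dynamic_indices(model)
    y[dyn] = np.where(y[dyn] < 0, np.where(y[dyn] > -atol * 10, 0.0, y[dyn]), y[dyn])

    v_ven_pl = model.venous_plasma_volume
    if model.skin_grid is not None and regimen.route == "dermal":
        area = model.application_area or 1.0
    else:
        area = 1.0
    amounts = {}
    for label, i in model.index.items():
        if label in ("cum_eliminated", "cum_absorbed"):
            continue
        series = y[i]
        if label.startswith("skin_"):
            series = series * area  # per-cm² states -> absolute µg
        amounts[label] = series

    plasma_ng_ml = y[model.index["venous.pl"]] / v_ven_pl * NG_PER_UG
    return SimulationResult(
        time=t,
        plasma_concentration=plasma_ng_ml,
        amounts=amounts,
        cumulative_eliminated=y[model.index["cum_eliminated"]],
        cumulative_absorbed=y[model.index["cum_absorbed"]],
        dose_administered=administered,
        cumulative_administered=administered_t,
        metadata={
            "solver": method, "rtol": rtol, "atol": atol,
            "route": regimen.route, "n_events": len(events),
        },
    )


def auc_infinity(model: PBKModel, initial_state: np.ndarray) -> float:
    """Exact AUC(0–∞) of venous plasma concentration, ng·h/mL.

    For the linear system dx/dt = A x with x(0) = x0, the time integral of
    the state is −A⁻¹x0 (A restricted to the mass-carrying block, which is
    Hurwitz whenever clearance is non-zero), so the AUC needs no long
    simulation or extrapolation.
    """
    dyn = _dynamic_indices(model)
    a_dyn = model.matrix[np.ix_(dyn, dyn)]
    x0 = np.asarray(initial_state, dtype=float)[dyn]
    try:
        integral = np.linalg.solve(a_dyn, -x0)
    except np.linalg.LinAlgError as exc:
        raise SimulationError(f"AUC(0–∞) undefined: singular system ({exc})")
    pos = int(np.where(dyn == model.index["venous.pl"])[0][0])
    return float(integral[pos]) / model.venous_plasma_volume * NG_PER_UG


def plasma_concentration_at(
    model: PBKModel,
    dose_mg_kg: float,
    times: np.ndarray,
    route: str = "iv_bolus",
) -> np.ndarray:
    """Exact venous plasma concentration (ng/mL) at arbitrary times after a
    single dose, by stepping the linear system with matrix exponentials.

    Cheaper and exact compared to interpolating a dense simulation; used by
    the identification loop and the synthetic-data generators.
    """
    t = np.asarray(times, dtype=float)
    order = np.argsort(t)
    if route == "iv_bolus":
        x = iv_bolus_state(model, dose_mg_kg)
    elif route == "oral":
        if model.oral_spec is None:
            raise ConstructionError("oral route requires an oral spec")
        x = np.zeros(model.n_states)
        x[model.index["gut_lumen"]] = (dose_mg_kg
                                       * model.individual.body_weight
                                       * UG_PER_MG)
    else:
        raise ValidationError(f"unsupported route {route!r}")
    a = model.matrix
    i_ven = model.index["venous.pl"]
    conc = np.empty(len(t))
    t_prev = 0.0
    for k in order:
        dt = t[k] - t_prev
        if dt > 0:
            x = expm(a * dt) @ x
            t_prev = t[k]
        conc[k] = x[i_ven] / model.venous_plasma_volume * NG_PER_UG
    return conc


def iv_bolus_state(model: PBKModel, dose_mg_kg: float) -> np.ndarray:
    x0 = np.zeros(model.n_states)
    x0[model.index["venous.pl"]] = (dose_mg_kg * model.individual.body_weight
                                    * UG_PER_MG)
    return x0


def clint_from_halflife(half_life: float, cell_density: float) -> float:
    """Intrinsic clearance (µL/min/10⁶ cells) from an in vitro half-life.

    CL_int = ln 2 / t½ · 1000 µL/mL / cell density (10⁶ cells/mL).
    11.64 min at 1×10⁶ cells/mL gives 59.6 µL/min/10⁶ cells.
    """
    if half_life <= 0 or cell_density <= 0:
        raise RangeError("half_life and cell_density must be > 0")
    return math.log(2.0) / half_life * 1000.0 / cell_density


def ivive_hepatic_clearance(
    clint: float,
    liver_mass: float,
    hepatocellularity: float = DEFAULT_HEPATOCELLULARITY,
    fu: float = 1.0,
    liver_blood_flow: float = 90.0,
    blood_plasma_ratio: float = 1.0,
) -> float:
    """Well-stirred hepatic plasma clearance (L/h) from in vitro CL_int.

    Whole-liver intrinsic clearance CL_int,liver = clint (µL/min/10⁶ cells)
    × hepatocellularity (10⁶ cells/g) × liver mass (g), converted to L/h,
    then combined with total liver blood flow Q (L/h) and the unbound
    fraction by CL_h = Q · fu·CL_int/R_b / (Q + fu·CL_int/R_b), with R_b the
    blood:plasma concentration ratio. As CL_int → ∞ the clearance
    approaches liver blood flow; fu = 0 gives zero.
    """
    if min(clint, liver_mass, hepatocellularity, liver_blood_flow,
           blood_plasma_ratio) < 0 or not (0.0 <= fu <= 1.0):
        raise RangeError("all IVIVE inputs must be non-negative and fu in [0, 1]")
    clint_whole_l_h = clint * hepatocellularity * liver_mass * MIN_PER_H / 1.0e6
    num = liver_blood_flow * fu * clint_whole_l_h / blood_plasma_ratio
    den = liver_blood_flow + fu * clint_whole_l_h / blood_plasma_ratio
    if den == 0.0:
        return 0.0
    return num / den


def calibrate_oral_absorption(
    model: PBKModel,
    regimen: DoseRegimen,
    target_fb: float,
    bounds: tuple[float, float] = (1.0e-6, 10.0),
) -> OralAbsorptionSpec:
    """Find the intestinal permeability giving a target oral bioavailability.

    Fb is (AUC_oral · Dose_iv)/(AUC_iv · Dose_oral), evaluated with the exact
    linear-system AUC(0–∞) at each candidate permeability, and solved by
    monotone root search over ``bounds`` (cm/min). Returns the calibrated
    absorption spec reporting the achieved Fa.
    """
    if model.oral_spec is None:
        raise ConstructionError("model has no oral absorption configured")
    if not (0.0 < target_fb <= 1.0):
        raise RangeError("target_fb must be in (0, 1]")

    base_spec = model.oral_spec
    from dataclasses import replace as dc_replace

    auc_iv = auc_infinity(model, iv_bolus_state(model, 1.0))  # per 1 mg/kg

    def fb_for(perm: float) -> float:
        spec = dc_replace(base_spec, intestinal_permeability=perm)
        m = build_model(model.individual, model.substance, model.partition_set,
                        model.clearance_spec, oral_spec=spec,
                        options=model.options)
        x0 = np.zeros(m.n_states)
        x0[m.index["gut_lumen"]] = model.individual.body_weight * UG_PER_MG  # 1 mg/kg
        return auc_infinity(m, x0) / auc_iv

    lo, hi = bounds
    fb_lo, fb_hi = fb_for(lo), fb_for(hi)
    if not (min(fb_lo, fb_hi) <= target_fb <= max(fb_lo, fb_hi)):
        if abs(fb_hi - target_fb) / target_fb <= 0.01:
            perm = hi
        else:
            raise CalibrationError(
                f"target Fb {target_fb} outside reachable range "
                f"[{fb_lo:.4g}, {fb_hi:.4g}] for permeability bounds {bounds}",
                bracket=(fb_lo, fb_hi),
            )
    else:
        perm = brentq(lambda p: fb_for(p) - target_fb, lo, hi, rtol=1e-9)
    achieved_fb = fb_for(perm)
    if abs(achieved_fb - target_fb) > 0.01 * target_fb:
        raise CalibrationError(
            f"calibrated Fb {achieved_fb:.4g} misses target {target_fb:.4g}")
    spec = dc_replace(base_spec, intestinal_permeability=perm,
                      bioavailability_target=target_fb,
                      fraction_absorbed_target=None)
    return spec
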