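"""Local one-at-a-time sensitivity of PK endpoints with WHO classification.

The sensitivity of an endpoint PK to an input parameter p is the ratio of
relative changes, S = (ΔPK/PK)/(Δp/p), evaluated on a ladder of
perturbations (default five steps of ±10%) and averaged. |S| bands follow
the WHO guideline: high ≥ 0.5, medium ≥ 0.2, low ≥ 0.1, below that
negligible (such parameters are suppressed from the default report view).

Note the estimator's finite-step property: for endpoints exactly
proportional to the parameter S is 1 for any step size, while curved
relationships (e.g. AUC ∝ 1/CL) carry an O(δ²) bias that vanishes as the
step shrinks; ``step_fraction`` is configurable for that reason.

Parameters are addressed as dotted names: ``substance.<field>``,
``clearance.<field>``, ``individual.<field>``, ``oral.<field>`` or the
special name ``dose``. Perturbing a substance field rebuilds the partition
set when (and only when) the field can affect it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .distribution import build_partition_set
from .errors import ValidationError
from .metrics import compute_metrics
from .pbk import (DoseRegimen, PBKModel, auc_infinity, build_model,
                  iv_bolus_state, simulate)

log = logging.getLogger(__name__)

ENDPOINTS = ("cmax", "auc_0_24", "auc_inf")

#: substance fields whose change invalidates the cached partition set
_PARTITION_FIELDS = {"fraction_unbound", "log_p", "pka", "ionization_class"}

CLASS_BANDS = (("high", 0.5), ("medium", 0.2), ("low", 0.1))


def classify(s: float) -> str:
    """WHO sensitivity class from |S|: high ≥0.5, medium ≥0.2, low ≥0.1."""
    if not np.isfinite(s):
        raise ValidationError("sensitivity must be finite")
    a = abs(s)
    for name, bound in CLASS_BANDS:
        if a >= bound:
            return name
    return "negligible"


@dataclass
class SensitivityResult:
    parameter: str
    endpoint: str
    sensitivity: float
    per_step: list[float]
    classification: str


def _perturbed_model(model: PBKModel, parameter: str, factor: float) -> PBKModel:
    """Rebuild the model with one parameter scaled by ``factor``."""
    scope, _, field = parameter.partition(".")
    substance, individual = model.substance, model.individual
    clearance, oral = model.clearance_spec, model.oral_spec
    pset = model.partition_set

    if scope == "substance":
        new_value = getattr(substance, field) * factor
        substance = substance.replace(**{field: new_value})
        if field in _PARTITION_FIELDS:
            pset = build_partition_set(substance, individual)
    elif scope == "clearance":
        clearance = dc_replace(clearance, **{field: getattr(clearance, field) * factor})
    elif scope == "individual":
        import dataclasses
        individual = dataclasses.replace(
            individual, **{field: getattr(individual, field) * factor})
        pset = build_partition_set(substance, individual)
    elif scope == "oral":
        if oral is None:
            raise ValidationError("model has no oral absorption spec")
        oral = dc_replace(oral, **{field: getattr(oral, field) * factor})
    else:
        raise ValidationError(
            f"cannot perturb {parameter!r}: use 'dose' or a dotted name "
            "substance.*, clearance.*, individual.* or oral.*")

    new = build_model(individual, substance, pset, clearance,
                      oral_spec=oral, options=model.options)
    if model.skin_grid is not None:
        from .pbk import couple_to_systemic
        new = couple_to_systemic(new, model.skin_grid, model.application_area)
    return new


def _endpoint_value(model: PBKModel, regimen: DoseRegimen, endpoint: str,
                    t_end: float) -> float:
    """Evaluate one endpoint; uses the exact linear-system AUC(0–∞) for a
    single IV bolus, otherwise simulates."""
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}; one of {ENDPOINTS}")
    single = len(regimen.event_times()) == 1
    if endpoint == "auc_inf" and single and regimen.route == "iv_bolus":
        return auc_infinity(model, iv_bolus_state(model, regimen.dose))
    result = simulate(model, regimen, t_end=t_end)
    window = (max(0.0, t_end - 24.0), t_end) if t_end > 24.0 else (0.0, t_end)
    m = compute_metrics(result, window=window)
    if endpoint == "cmax":
        return m.cmax
    if endpoint == "auc_0_24":
        return m.auc_0_24
    if m.auc_inf is None:
        raise ValidationError(f"AUC(0–∞) not extrapolatable: {m.auc_inf_reason}")
    return m.auc_inf


def local_sensitivity(
    model: PBKModel,
    regimen: DoseRegimen,
    parameter: str,
    endpoint: str = "cmax",
    n_steps: int = 5,
    step_fraction: float = 0.10,
    t_end: float = 24.0,
    one_sided: bool = False,
) -> SensitivityResult:
    """Average relative sensitivity over a ±k·step perturbation ladder.

    For k = 1..n_steps the parameter is scaled by (1 ± k·step_fraction)
    (symmetric by default; ``one_sided`` keeps only the + side), the
    endpoint is recomputed and S_k = (ΔPK/PK)/(Δp/p); steps whose
    perturbation violates a model invariant (e.g. Fu > 1) are skipped with
    a log message. S is the mean of the valid S_k.
    """
    pk0 = _dose_aware_endpoint(model, regimen, parameter, 1.0, endpoint, t_end)
    if pk0 == 0:
        raise ValidationError("baseline endpoint is zero; S undefined")
    per_step: list[float] = []
    signs = (1.0,) if one_sided else (1.0, -1.0)
    for k in range(1, n_steps + 1):
        delta = k * step_fraction
        for sign in signs:
            factor = 1.0 + sign * delta
            if factor <= 0:
                log.warning("skipping step %+g for %s: non-positive factor",
                            sign * delta, parameter)
                continue
            try:
                pk = _dose_aware_endpoint(model, regimen, parameter, factor,
                                          endpoint, t_end)
            except (ValidationError, ValueError) as exc:
                log.warning("skipping step %+g for %s: %s", sign * delta,
                            parameter, exc)
                continue
            per_step.append(((pk - pk0) / pk0) / (sign * delta))
    if not per_step:
        raise ValidationError(f"all perturbation steps invalid for {parameter!r}")
    s = float(np.mean(per_step))
    return SensitivityResult(parameter=parameter, endpoint=endpoint,
                             sensitivity=s, per_step=per_step,
                             classification=classify(s))


def _dose_aware_endpoint(model: PBKModel, regimen: DoseRegimen,
                         parameter: str, factor: float, endpoint: str,
                         t_end: float) -> float:
    if parameter == "dose":
        regimen = dc_replace(regimen, dose=regimen.dose * factor)
    elif factor != 1.0:
        model = _perturbed_model(model, parameter, factor)
    return _endpoint_value(model, regimen, endpoint, t_end)


@dataclass
class SensitivityReport:
    """Ranked sensitivity table; ``table`` keeps everything, ``significant``
    suppresses |S| < 0.1 entries (the default view)."""

    table: pd.DataFrame
    endpoint: str

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["classification"] != "negligible"].reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sensitivity_report(
    model: PBKModel,
    regimen: DoseRegimen,
    parameters: list[str],
    endpoint: str = "cmax",
    n_steps: int = 5,
    step_fraction: float = 0.10,
    t_end: float = 24.0,
) -> SensitivityReport:
    """Run local_sensitivity over a parameter list, ranked by |S| descending."""
    if not parameters:
        raise ValidationError("at least one parameter required")
    if len(set(parameters)) != len(parameters):
        raise ValidationError("duplicate parameter names in sensitivity request")
    rows = []
    for p in parameters:
        r = local_sensitivity(model, regimen, p, endpoint=endpoint,
                              n_steps=n_steps, step_fraction=step_fraction,
                              t_end=t_end)
        rows.append({"parameter": p, "S": r.sensitivity,
                     "classification": r.classification})
    df = pd.DataFrame(rows)
    df["abs_S"] = df["S"].abs()
    df = df.sort_values("abs_S", ascending=False).drop(columns="abs_S")
    return SensitivityReport(table=df.reset_index(drop=True), endpoint=endpoint)
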