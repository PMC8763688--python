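"""Monte-Carlo parameter identification against concentration-time data.

A pure seeded random search: candidate parameter sets are drawn uniformly
(in linear or log space) inside bounds, the model is simulated at the
observed times, and the best set under the loss is kept. The default loss
is the sum of squared residuals in log concentration — IV washout spans
orders of magnitude, so a linear loss would see only the first points.
Observations below a configurable limit of quantification are excluded.

No gradient or evolutionary refinement is applied by default; an optional
Nelder–Mead polish can be switched on but is off for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import FitError, ValidationError
from .metrics import window_auc
from .pbk import DoseRegimen, PBKModel, simulate

LOSSES = ("sse_log", "sse_linear")


@dataclass(frozen=True)
class FitParameter:
    name: str
    lower: float
    upper: float
    transform: str = "linear"   # or "log"

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.upper):
            raise ValidationError(
                f"{self.name}: bounds must be positive and ordered, "
                f"got ({self.lower}, {self.upper})")
        if self.transform not in ("linear", "log"):
            raise ValidationError(f"{self.name}: unknown transform {self.transform!r}")

    def draw(self, rng: np.random.Generator) -> float:
        if self.transform == "log":
            return float(np.exp(rng.uniform(np.log(self.lower), np.log(self.upper))))
        return float(rng.uniform(self.lower, self.upper))


@dataclass(frozen=True)
class FitSpec:
    parameters: tuple[FitParameter, ...]
    n_iterations: int = 1000
    seed: int = 0
    loss: str = "sse_log"
    loq: float = 0.0            # ng/mL; observations below are dropped
    polish: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.loss not in LOSSES:
            raise ValidationError(f"loss must be one of {LOSSES}")
        if not self.parameters:
            raise ValidationError("at least one parameter to fit")


@dataclass
class FitResult:
    best_params: dict[str, float]
    loss: float
    trace: np.ndarray           # best-so-far loss per iteration
    n_evaluated: int
    n_failed: int
    seed: int

    def to_json_dict(self) -> dict:
        return {"best_params": self.best_params, "loss": self.loss,
                "n_evaluated": self.n_evaluated, "n_failed": self.n_failed,
                "seed": self.seed}


def _validate_observed(observed: pd.DataFrame, loq: float) -> pd.DataFrame:
    required = {"time_h", "conc_ng_ml"}
    if not required <= set(observed.columns):
        raise ValidationError(f"observed data needs columns {sorted(required)}")
    obs = observed[observed["conc_ng_ml"] > max(loq, 0.0)].copy()
    if len(obs) < 3:
        raise ValidationError("need >= 3 observations above the LOQ")
    if (obs["conc_ng_ml"] <= 0).any():
        raise ValidationError("observed concentrations must be > 0")
    if "dose_mg_kg" not in obs.columns:
        obs["dose_mg_kg"] = np.nan
    return obs


def _predict(model: PBKModel, obs_group: pd.DataFrame, dose: float,
             route: str) -> np.ndarray:
    """Venous plasma concentration at the observed times (single dose)."""
    from .pbk import plasma_concentration_at

    t_obs = np.asarray(obs_group["time_h"], dtype=float)
    return plasma_concentration_at(model, dose, t_obs, route)


def _loss_value(pred: np.ndarray, obs: np.ndarray, loss: str) -> float:
    if loss == "sse_log":
        pred = np.clip(pred, 1e-12, None)
        return float(np.sum((np.log(pred) - np.log(obs)) ** 2))
    return float(np.sum((pred - obs) ** 2))


def fit(
    model_factory: Callable[[dict[str, float]], PBKModel],
    observed: pd.DataFrame,
    spec: FitSpec,
    route: str = "iv_bolus",
) -> FitResult:
    """Seeded Monte-Carlo random search over the parameter bounds.

    ``model_factory`` maps a parameter dict to a ready PBKModel;
    ``observed`` needs columns time_h, conc_ng_ml and (for multi-dose data)
    dose_mg_kg. Deterministic given ``spec.seed``.
    """
    obs = _validate_observed(observed, spec.loq)
    rng = np.random.default_rng(spec.seed)
    groups = list(obs.groupby("dose_mg_kg", dropna=False))

    def evaluate(params: dict[str, float]) -> float:
        model = model_factory(params)
        total = 0.0
        for dose, g in groups:
            d = 1.0 if np.isnan(dose) else float(dose)
            pred = _predict(model, g, d, route)
            total += _loss_value(pred, g["conc_ng_ml"].to_numpy(), spec.loss)
        return total

    best_params: dict[str, float] | None = None
    best_loss = np.inf
    trace = np.empty(spec.n_iterations)
    failures: list[str] = []
    for i in range(spec.n_iterations):
        params = {p.name: p.draw(rng) for p in spec.parameters}
        try:
            loss = evaluate(params)
        except Exception as exc:  # noqa: BLE001 — failed draws are recorded
            failures.append(f"{params}: {exc}")
            trace[i] = best_loss
            continue
        if loss < best_loss:
            best_loss, best_params = loss, params
        trace[i] = best_loss
    if best_params is None:
        raise FitError(
            "all parameter draws failed; first failures: "
            + "; ".join(failures[:3]))

    if spec.polish:
        names = [p.name for p in spec.parameters]
        x0 = np.array([best_params[n] for n in names])
        res = minimize(lambda x: evaluate(dict(zip(names, x))), x0,
                       method="Nelder-Mead")
        if res.fun < best_loss:
            best_loss = float(res.fun)
            best_params = dict(zip(names, res.x))

    return FitResult(best_params=best_params, loss=float(best_loss),
                     trace=trace, n_evaluated=spec.n_iterations,
                     n_failed=len(failures), seed=spec.seed)


@dataclass
class GoodnessProfile:
    residuals: pd.DataFrame
    cmax_ratio: float
    auc_ratio: float

    def acceptable(self, fold: float = 1.25) -> bool:
        """Fold-error acceptance (default: both ratios within [1/1.25, 1.25])."""
        lo, hi = 1.0 / fold, fold
        return lo <= self.cmax_ratio <= hi and lo <= self.auc_ratio <= hi


def goodness_profile(
    model_factory: Callable[[dict[str, float]], PBKModel],
    params: dict[str, float],
    observed: pd.DataFrame,
    route: str = "iv_bolus",
) -> GoodnessProfile:
    """Per-point residuals plus predicted/observed C_max and AUC ratios."""
    obs = _validate_observed(observed, 0.0)
    model = model_factory(params)
    frames = []
    for dose, g in obs.groupby("dose_mg_kg", dropna=False):
        d = 1.0 if np.isnan(dose) else float(dose)
        pred = _predict(model, g, d, route)
        frames.append(pd.DataFrame({
            "time_h": g["time_h"].to_numpy(),
            "dose_mg_kg": d,
            "observed": g["conc_ng_ml"].to_numpy(),
            "predicted": pred,
        }))
    table = pd.concat(frames, ignore_index=True)
    table["residual"] = table["predicted"] - table["observed"]
    table["log_residual"] = np.log(np.clip(table["predicted"], 1e-12, None)) \
        - np.log(table["observed"])

    cmax_ratio = float(table["predicted"].max() / table["observed"].max())
    auc_obs = auc_pred = 0.0
    for _, g in table.groupby("dose_mg_kg"):
        g = g.sort_values("time_h")
        if g["time_h"].nunique() < 2:
            continue
        span = (float(g["time_h"].min()), float(g["time_h"].max()))
        tt = g["time_h"].to_numpy()
        auc_obs += window_auc(tt, g["observed"].to_numpy(), span)
        auc_pred += window_auc(tt, g["predicted"].to_numpy(), span)
    auc_ratio = float(auc_pred / auc_obs) if auc_obs > 0 else np.nan
    return GoodnessProfile(residuals=table, cmax_ratio=cmax_ratio,
                           auc_ratio=auc_ratio)
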