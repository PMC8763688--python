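"""Virtual populations and parameter-uncertainty Monte Carlo.

A virtual population samples body weight (and age, for humans) over the
stated ranges — uniformly by default, since the source protocol states only
the ranges; a truncated-normal option exists. Physiology co-varies with
body weight by isometric organ scaling (see :mod:`homopbk.physiology`).

Parameter uncertainty draws truncated-normal values per substance-specific
parameter (e.g. Fu 2 ± 0.2%), independent across parameters, resampling any
draw outside its truncation bounds. Population variability and parameter
uncertainty are combined in a single Monte-Carlo layer: individual i gets
physiology i and parameter draw i.

Summaries report the mean and the empirical 5th/95th percentiles
(linear-interpolation, numpy default, i.e. type-7), the convention recorded
in every result object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import RangeError, ValidationError
from .metrics import PKMetrics, compute_metrics
from .pbk import DoseRegimen, PBKModel, simulate
from .physiology import Individual, build_individual

PERCENTILE_DEFINITION = "empirical 5th/95th, linear interpolation (type 7)"


@dataclass(frozen=True)
class PopulationSpec:
    """Virtual-population design: species, size, ranges and seed."""

    species: str
    n_individuals: int = 100
    rat_bw_range: tuple[float, float] = (0.185, 0.275)
    human_age_range: tuple[float, float] = (16.0, 70.0)
    human_bw_range: tuple[float, float] = (45.0, 100.0)
    seed: int = 0
    distribution: str = "uniform"    # or "normal" (truncated, sd = range/4)

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValidationError("n_individuals must be >= 2")
        for rng_ in (self.rat_bw_range, self.human_age_range, self.human_bw_range):
            if rng_[0] > rng_[1]:
                raise ValidationError(f"range {rng_} must be ordered")
        if self.distribution not in ("uniform", "normal"):
            raise ValidationError(f"unknown distribution {self.distribution!r}")


def _sample_range(rng: np.random.Generator, lo: float, hi: float, n: int,
                  distribution: str) -> np.ndarray:
    if lo == hi:
        return np.full(n, lo)
    if distribution == "uniform":
        return rng.uniform(lo, hi, n)
    mean, sd = 0.5 * (lo + hi), (hi - lo) / 4.0
    out = np.empty(n)
    for i in range(n):
        v = rng.normal(mean, sd)
        while not (lo <= v <= hi):
            v = rng.normal(mean, sd)
        out[i] = v
    return out


def generate_population(spec: PopulationSpec) -> list[Individual]:
    """Seeded sampling of individuals; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    if spec.species == "rat":
        bws = _sample_range(rng, *spec.rat_bw_range, n, spec.distribution)
        return [build_individual("rat", {"body_weight": float(b)}) for b in bws]
    bws = _sample_range(rng, *spec.human_bw_range, n, spec.distribution)
    ages = _sample_range(rng, *spec.human_age_range, n, spec.distribution)
    return [
        build_individual("human", {"body_weight": float(b), "age": float(a)})
        for b, a in zip(bws, ages)
    ]


@dataclass(frozen=True)
class UncertainParameter:
    """Truncated-normal spec for one parameter (mean, sd, bounds)."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf
    distribution: str = "normal"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise RangeError("sd must be >= 0")
        if not (self.lower <= self.mean <= self.upper):
            raise ValidationError(
                f"truncation bounds ({self.lower}, {self.upper}) exclude "
                f"mean {self.mean}")
        if self.distribution != "normal":
            raise ValidationError("only normal uncertainty is supported")


#: UncertaintySpec: parameter name -> UncertainParameter
UncertaintySpec = dict[str, UncertainParameter]


def sample_uncertain_parameters(
    spec: UncertaintySpec, n: int, seed: int = 0
) -> pd.DataFrame:
    """Independent truncated-normal draws; out-of-bound draws are resampled."""
    rng = np.random.default_rng(seed)
    data = {}
    for name, p in spec.items():
        if p.sd == 0:
            data[name] = np.full(n, p.mean)
            continue
        draws = np.empty(n)
        for i in range(n):
            v = rng.normal(p.mean, p.sd)
            while not (p.lower <= v <= p.upper):
                v = rng.normal(p.mean, p.sd)
            draws[i] = v
        data[name] = draws
    return pd.DataFrame(data)


@dataclass
class PopulationResult:
    """Per-individual metrics plus mean/CI(5–95)% summary."""

    per_individual: pd.DataFrame
    summary: dict[str, dict[str, float]]
    n: int
    n_failed: int
    seed: int | None
    percentile_definition: str = PERCENTILE_DEFINITION

    def write_csv(self, path) -> None:
        self.per_individual.to_csv(path, index=False)

    def summary_json_dict(self) -> dict:
        return {"summary": self.summary, "n": self.n, "n_failed": self.n_failed,
                "seed": self.seed,
                "percentile_definition": self.percentile_definition}


def summarize_metrics(per_individual: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Mean and CI(5–95)% per endpoint column present in the frame."""
    out = {}
    for col in ("cmax", "auc_0_24", "auc_inf"):
        if col not in per_individual.columns:
            continue
        vals = per_individual[col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        out[col] = {
            "mean": float(vals.mean()),
            "ci5": float(np.percentile(vals, 5)),
            "ci95": float(np.percentile(vals, 95)),
        }
    return out


def population_simulate(
    build_fn: Callable[[Individual, dict[str, float]], PBKModel],
    regimen: DoseRegimen,
    population: list[Individual],
    parameter_draws: pd.DataFrame | None = None,
    t_end: float = 24.0,
    window: tuple[float, float] | None = None,
    seed: int | None = None,
) -> PopulationResult:
    """Simulate every individual and summarize the endpoint distribution.

    ``build_fn(individual, draws_row)`` returns the ready model (the caller
    decides how parameter draws map onto substance/clearance fields and
    whether a skin grid is coupled). Individuals whose simulation fails are
    excluded and counted in ``n_failed``.
    """
    if parameter_draws is not None and len(parameter_draws) != len(population):
        raise ValidationError(
            "parameter_draws must have one row per individual "
            f"({len(parameter_draws)} rows vs {len(population)} individuals)")
    if window is None:
        window = (max(0.0, t_end - 24.0), t_end)
    rows = []
    n_failed = 0
    for i, individual in enumerate(population):
        draws = ({} if parameter_draws is None
                 else parameter_draws.iloc[i].to_dict())
        try:
            model = build_fn(individual, draws)
            result = simulate(model, regimen, t_end=t_end)
            m = compute_metrics(result, window=window)
        except Exception:  # noqa: BLE001 — failures flagged, not fatal
            n_failed += 1
            continue
        rows.append({
            "individual": i,
            "body_weight": individual.body_weight,
            "age": individual.age,
            "cmax": m.cmax, "tmax": m.tmax,
            "auc_0_24": m.auc_0_24, "auc_inf": m.auc_inf,
            **{f"draw_{k}": v for k, v in draws.items()},
        })
    if not rows:
        raise ValidationError("every individual simulation failed")
    per_individual = pd.DataFrame(rows)
    return PopulationResult(
        per_individual=per_individual,
        summary=summarize_metrics(per_individual),
        n=len(rows), n_failed=n_failed, seed=seed,
    )
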