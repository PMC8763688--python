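"""Non-compartmental endpoint extraction and margin-of-internal-exposure.

C_max/T_max come from the dense simulation grid; windowed AUC uses the
trapezoid rule; AUC(0–∞) adds a terminal extrapolation C_last/λz with λz
fitted by log-linear regression on the final third of the post-T_max decline
(minimum 3 points, standard NCA practice). T_max ties break to the earliest
time. The MoIE is the ratio of a point-of-departure internal metric to the
predicted human internal metric, compared to a safety-factor threshold of 25
(the WHO decomposition 2.5 × 3.16 × 3.16).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RangeError, ValidationError
from .pbk import SimulationResult

#: default MoIE safety threshold: 2.5 (interspecies TD) × 3.16 (human TD)
#: × 3.16 (human TK)
MOIE_THRESHOLD = 25.0


@dataclass
class PKMetrics:
    """Endpoints of one simulated (or observed) concentration-time course."""

    cmax: float                     # ng/mL
    tmax: float                     # h
    auc_0_24: float                 # ng·h/mL over the requested window
    auc_inf: float | None = None    # ng·h/mL, None if extrapolation refused
    auc_inf_reason: str | None = None
    accumulation_ratio: float | None = None
    window: tuple[float, float] = (0.0, 24.0)

    def __post_init__(self) -> None:
        if self.cmax < 0 or self.auc_0_24 < 0:
            raise RangeError("metrics must be non-negative")
        if self.auc_inf is not None and self.auc_inf < self.auc_0_24 * (1 - 1e-9) \
                and self.window[0] == 0.0:
            raise ValidationError("AUC(0–∞) cannot be below AUC over a "
                                  "window starting at t = 0")


def window_auc(time: np.ndarray, conc: np.ndarray,
               window: tuple[float, float]) -> float:
    """Trapezoid AUC over [a, b], interpolating the window endpoints."""
    a, b = window
    if b <= a:
        raise ValidationError(f"empty AUC window {window}")
    if a < time[0] - 1e-9 or b > time[-1] + 1e-9:
        raise ValidationError(f"window {window} outside simulated span "
                              f"[{time[0]}, {time[-1]}]")
    inside = (time > a) & (time < b)
    tt = np.concatenate(([a], time[inside], [b]))
    cc = np.concatenate(([np.interp(a, time, conc)], conc[inside],
                         [np.interp(b, time, conc)]))
    return float(np.trapezoid(cc, tt))


def terminal_slope(time: np.ndarray, conc: np.ndarray,
                   min_points: int = 3) -> tuple[float | None, str | None]:
    """λz (1/h) from log-linear regression on the terminal decline.

    Uses the final third of post-T_max points (at least ``min_points``).
    Returns (None, reason) if the terminal phase is not a decline.
    """
    i_max = int(np.argmax(conc))
    post = np.arange(i_max + 1, len(time))
    post = post[conc[post] > 0]
    if len(post) < min_points:
        return None, "fewer than %d positive post-T_max points" % min_points
    n_fit = max(min_points, len(post) // 3)
    sel = post[-n_fit:]
    slope, _ = np.polyfit(time[sel], np.log(conc[sel]), 1)
    if slope >= 0:
        return None, "terminal phase not declining (lambda_z <= 0)"
    return float(-slope), None


def compute_metrics(
    result: SimulationResult,
    window: tuple[float, float] = (0.0, 24.0),
    terminal_fit_points: int = 3,
) -> PKMetrics:
    """Extract C_max, T_max, windowed AUC and extrapolated AUC(0–∞)."""
    t = result.time
    c = result.plasma_concentration
    i_max = int(np.argmax(c))     # argmax returns the first maximum: earliest
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc_w = window_auc(t, c, window)

    lam, reason = terminal_slope(t, c, min_points=terminal_fit_points)
    if lam is None:
        auc_inf, inf_reason = None, reason
    else:
        auc_last = window_auc(t, c, (t[0], t[-1]))
        auc_inf = auc_last + float(c[-1]) / lam
        inf_reason = None
    return PKMetrics(cmax=cmax, tmax=tmax, auc_0_24=auc_w,
                     auc_inf=auc_inf, auc_inf_reason=inf_reason,
                     window=window)


def accumulation_ratio(result: SimulationResult, interval: float = 24.0,
                       first_start: float = 0.0,
                       last_start: float | None = None) -> float:
    """C_max ratio between the last and first dosing window."""
    t, c = result.time, result.plasma_concentration
    if last_start is None:
        last_start = t[-1] - interval
    first = c[(t >= first_start) & (t <= first_start + interval)]
    last = c[(t >= last_start) & (t <= last_start + interval)]
    if len(first) == 0 or len(last) == 0 or first.max() == 0:
        raise ValidationError("windows empty or first-window C_max is zero")
    return float(last.max() / first.max())


@dataclass
class DoseLinearityResult:
    """Dose-normalized slopes and the worst pairwise proportionality error."""

    slope_cmax: float               # ng/mL per mg/kg (or per µg/cm²)
    slope_auc: float
    max_proportionality_error: float
    ratios: pd.DataFrame = field(repr=False, default=None)


def dose_linearity(metrics: list[tuple[float, PKMetrics]]) -> DoseLinearityResult:
    """Check proportionality of C_max and windowed AUC with dose."""
    if len(metrics) < 2:
        raise ValidationError("dose_linearity needs at least 2 dose levels")
    doses = np.array([d for d, _ in metrics], dtype=float)
    if np.any(doses <= 0):
        raise RangeError("doses must be > 0")
    cmax_ratio = np.array([m.cmax for _, m in metrics]) / doses
    auc_ratio = np.array([m.auc_0_24 for _, m in metrics]) / doses

    def spread(r: np.ndarray) -> float:
        return float((r.max() - r.min()) / r.mean()) if r.mean() > 0 else 0.0

    table = pd.DataFrame({"dose": doses, "cmax_per_dose": cmax_ratio,
                          "auc_per_dose": auc_ratio})
    return DoseLinearityResult(
        slope_cmax=float(cmax_ratio.mean()),
        slope_auc=float(auc_ratio.mean()),
        max_proportionality_error=max(spread(cmax_ratio), spread(auc_ratio)),
        ratios=table,
    )


@dataclass(frozen=True)
class MoIEResult:
    ratio: float
    threshold: float
    passes: bool
    metric_kind: str


def compute_moie(
    pod_metric: float,
    human_metric: float,
    threshold: float = MOIE_THRESHOLD,
    pod_kind: str = "auc_0_24",
    human_kind: str = "auc_0_24",
) -> MoIEResult:
    """Margin of internal exposure: PoD internal metric / human internal metric.

    Both metrics must be of the same kind (both AUCs or both C_max) and
    positive; the margin passes when it meets or exceeds the threshold.
    """
    if pod_kind != human_kind:
        raise ValidationError(
            f"metric kinds differ: {pod_kind!r} vs {human_kind!r}")
    if pod_metric <= 0 or human_metric <= 0:
        raise RangeError("both metrics must be > 0")
    ratio = pod_metric / human_metric
    return MoIEResult(ratio=ratio, threshold=threshold,
                      passes=ratio >= threshold, metric_kind=pod_kind)
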