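"""Thermal sensitivity (Q10) analysis and MRD classification.

The temperature quotient

    Q10 = (rate_cold / rate_warm) ** (10 / (T_cold - T_warm))

expresses how strongly a rate changes per 10 degC.  Passive Arrhenius
effects on ectotherm metabolism give Q10 ~ 2-3; a Q10 of SMR above 3.5
over a cooling interval is conventionally taken to indicate active
metabolic rate depression (MRD).  Arrhenius plots (ln rate vs 1/T_K) with
piecewise-linear breakpoint detection corroborate the Q10 analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MRD_Q10_THRESHOLD",
    "TemperatureInterval",
    "Q10Result",
    "ArrheniusFit",
    "q10",
    "q10_per_fish",
    "classify_mrd",
    "arrhenius_breakpoints",
    "q10_of_routine_vs_smr",
    "default_intervals",
]

#: conventional Q10 threshold above which MRD is inferred (strict >)
MRD_Q10_THRESHOLD = 3.5

_KELVIN = 273.15


@dataclass(frozen=True)
class TemperatureInterval:
    """A named warm-to-cold contrast between two experimental conditions."""

    label: str             # full_cooling | warm_half | cold_half | rewarming | acclimation
    condition_warm: str
    condition_cold: str
    t_warm_c: float        # nominal; per-fish actual temperatures preferred
    t_cold_c: float

    def __post_init__(self):
        if not self.t_warm_c > self.t_cold_c:
            raise ValueError("t_warm_c must exceed t_cold_c")


@dataclass
class Q10Result:
    """Per-fish and mean Q10 over one interval for one estimation method."""

    interval: TemperatureInterval
    method: str
    per_fish_q10: pd.Series = field(repr=False)
    mean_q10: float = float("nan")
    sem_q10: float = float("nan")
    n: int = 0
    n_dropped: int = 0
    threshold: float = MRD_Q10_THRESHOLD

    @property
    def mrd_flag(self) -> bool:
        return self.mean_q10 > self.threshold


def q10(rate_cold: float, temp_cold_c: float,
        rate_warm: float, temp_warm_c: float) -> float:
    """Temperature quotient of a rate over (temp_cold, temp_warm)."""
    if rate_cold <= 0 or rate_warm <= 0:
        raise ValueError("rates must be > 0")
    if temp_cold_c >= temp_warm_c:
        raise ValueError("temp_cold_c must be below temp_warm_c")
    return (rate_cold / rate_warm) ** (10.0 / (temp_cold_c - temp_warm_c))


def q10_per_fish(estimates: pd.DataFrame, intervals: list[TemperatureInterval],
                 method: str = "extrapolated_individual",
                 threshold: float = MRD_Q10_THRESHOLD) -> list[Q10Result]:
    """Q10 of per-fish SMR estimates over each interval.

    ``estimates`` is a tidy frame (scope, condition, temp_c, method,
    value).  Each fish's own endpoint temperatures and values are used;
    fish missing either endpoint are dropped with a logged count.
    """
    df = estimates[estimates["method"] == method]
    results = []
    for iv in intervals:
        warm = df[df["condition"] == iv.condition_warm].set_index("scope")
        cold = df[df["condition"] == iv.condition_cold].set_index("scope")
        common = warm.index.intersection(cold.index)
        dropped = len(warm.index.union(cold.index)) - len(common)
        if dropped:
            logger.info("interval %s: dropped %d fish missing an endpoint",
                        iv.label, dropped)
        vals = {}
        for fish in common:
            vals[fish] = q10(cold.loc[fish, "value"], cold.loc[fish, "temp_c"],
                             warm.loc[fish, "value"], warm.loc[fish, "temp_c"])
        per_fish = pd.Series(vals, dtype=float)
        if len(per_fish) < 2:
            logger.warning("interval %s: < 2 fish usable; no result", iv.label)
            results.append(Q10Result(iv, method, per_fish, n=len(per_fish),
                                     n_dropped=dropped, threshold=threshold))
            continue
        results.append(Q10Result(iv, method, per_fish,
                                 mean_q10=float(per_fish.mean()),
                                 sem_q10=float(per_fish.sem()),
                                 n=len(per_fish), n_dropped=dropped,
                                 threshold=threshold))
    return results


def classify_mrd(result: Q10Result,
                 threshold: float = MRD_Q10_THRESHOLD) -> tuple[bool, str]:
    """MRD verdict for one interval: flag plus human-readable text.

    The flag uses the strict inequality mean Q10 > threshold; a mean of
    exactly 3.5 is classified passive.  The verdict also reports the
    fraction of individual fish above the threshold, since individuals
    commonly straddle it.
    """
    flag = result.mean_q10 > threshold
    frac = float((result.per_fish_q10 > threshold).mean()) if result.n else float("nan")
    verdict = (
        f"{result.interval.label} [{result.method}]: mean Q10 = {result.mean_q10:.2f} "
        f"+/- {result.sem_q10:.2f} (n={result.n}); "
        f"{'MRD inferred' if flag else 'passive thermal effects'} "
        f"(threshold {threshold:g}); {frac:.0%} of fish above threshold"
    )
    return flag, verdict


@dataclass
class ArrheniusFit:
    """Arrhenius plot fit with 0-vs-1 breakpoint model selection."""

    temps_c: np.ndarray
    inv_t_k: np.ndarray
    ln_rate: np.ndarray
    breakpoint_c: float | None
    slopes: tuple[float, ...]     # segment slopes on the 1/T_K axis
    aicc_0break: float
    aicc_1break: float
    note: str = ""

    @property
    def has_breakpoint(self) -> bool:
        return self.breakpoint_c is not None


def _hinge_sse(x: np.ndarray, y: np.ndarray, xb: float):
    """SSE of the continuous one-hinge model y ~ 1 + x + max(x - xb, 0)."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - xb, 0.0)])
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    return float(np.sum((y - pred) ** 2)), beta


def _aicc(sse: float, n: int, k: int) -> float:
    # floor the SSE so noiseless data do not send the likelihood to -inf
    sse = max(sse, n * 1e-20)
    aic = n * np.log(sse / n) + 2 * k
    if n - k - 1 > 0:
        return aic + 2.0 * k * (k + 1) / (n - k - 1)
    return float("inf")


def arrhenius_breakpoints(mean_smr_by_temp: pd.DataFrame,
                          grid_step_c: float = 0.1) -> ArrheniusFit:
    """Detect at most one thermal-sensitivity breakpoint in SMR.

    Input: frame with columns ``temp_c`` and ``smr``.  The data are
    transformed to (1/T_K, ln SMR); a straight line and a continuous
    one-hinge piecewise line (break located by grid search over interior
    temperatures at ``grid_step_c`` resolution) are compared by
    small-sample-corrected AIC.  The breakpoint is reported in degC when
    the one-break model wins.
    """
    df = mean_smr_by_temp.sort_values("temp_c")
    temps = df["temp_c"].to_numpy(dtype=float)
    rates = df["smr"].to_numpy(dtype=float)
    if np.any(rates <= 0):
        raise ValueError("SMR values must be > 0")
    x = 1.0 / (temps + _KELVIN)
    y = np.log(rates)
    n = temps.size
    if n < 5:
        res = stats.linregress(x, y)
        return ArrheniusFit(temps, x, y, None, (float(res.slope),),
                            float("nan"), float("nan"),
                            "fewer than 5 temperatures; breakpoint not assessed")
    res = stats.linregress(x, y)
    sse0 = float(np.sum((y - (res.intercept + res.slope * x)) ** 2))
    aicc0 = _aicc(sse0, n, 2)

    lo, hi = temps.min(), temps.max()
    grid = np.arange(np.ceil((lo + grid_step_c) / grid_step_c) * grid_step_c,
                     hi - grid_step_c / 2, grid_step_c)
    # the hinge must have points on both sides to be identifiable
    grid = np.array([g for g in grid if (temps < g).sum() >= 2 and (temps > g).sum() >= 2])
    if grid.size == 0:
        return ArrheniusFit(temps, x, y, None, (float(res.slope),), aicc0,
                            float("inf"), "no admissible interior breakpoints")
    best = None
    for g in grid:
        xb = 1.0 / (g + _KELVIN)
        sse, beta = _hinge_sse(x, y, xb)
        if best is None or sse < best[0]:
            best = (sse, float(g), beta)
    sse1, break_c, beta = best
    aicc1 = _aicc(sse1, n, 4)
    if aicc1 < aicc0:
        # slopes on 1/T axis: cold side (large 1/T) has slope b1 + b2
        slopes = (float(beta[1]), float(beta[1] + beta[2]))
        return ArrheniusFit(temps, x, y, break_c, slopes, aicc0, aicc1)
    return ArrheniusFit(temps, x, y, None, (float(res.slope),), aicc0, aicc1,
                        "single Arrhenius slope preferred")


def q10_of_routine_vs_smr(estimates: pd.DataFrame,
                          intervals: list[TemperatureInterval],
                          methods: tuple[str, ...] = (
                              "extrapolated_individual", "lowest20_mo2",
                              "lowest20_activity", "overlap_band", "routine"),
                          ) -> pd.DataFrame:
    """Contrast routine-MR Q10 with each activity-controlled method.

    Returns a tidy frame (interval, method, mean_q10, sem_q10, n); missing
    methods/intervals propagate as absent rows.
    """
    rows = []
    for method in methods:
        if method not in set(estimates["method"]):
            continue
        for res in q10_per_fish(estimates, intervals, method=method):
            if res.n >= 2:
                rows.append((res.interval.label, method, res.mean_q10,
                             res.sem_q10, res.n))
    return pd.DataFrame(rows, columns=["interval", "method", "mean_q10",
                                       "sem_q10", "n"])


def default_intervals(temps_c, coldest_condition_prefix: str = "acute",
                      has_acclimation: bool = True) -> list[TemperatureInterval]:
    """Standard named intervals for an acute-cooling + acclimation protocol.

    full_cooling: warmest acute -> coldest acute; warm_half / cold_half
    split at the acute temperature nearest the midpoint; rewarming:
    acclimated coldest -> rewarmed; acclimation: warmest acute ->
    acclimated coldest.
    """
    temps = sorted((float(t) for t in temps_c), reverse=True)
    warmest, coldest = temps[0], temps[-1]
    mid_target = 0.5 * (warmest + coldest)
    mid = min(temps[1:-1], key=lambda t: abs(t - mid_target)) if len(temps) > 2 else None
    c = lambda t: f"acute_{t:g}"
    out = [TemperatureInterval("full_cooling", c(warmest), c(coldest), warmest, coldest)]
    if mid is not None:
        out.append(TemperatureInterval("warm_half", c(warmest), c(mid), warmest, mid))
        out.append(TemperatureInterval("cold_half", c(mid), c(coldest), mid, coldest))
    if has_acclimation:
        accl = f"acclimated_{coldest:g}"
        out.append(TemperatureInterval("acclimation", c(warmest), accl, warmest, coldest))
        out.append(TemperatureInterval("rewarming", "rewarmed", accl, warmest, coldest))
    return out
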