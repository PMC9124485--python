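"""Standard metabolic rate (SMR) estimation with activity control.

Spontaneous activity elevates oxygen uptake above SMR, and activity itself
falls with cooling, so uncontrolled metabolic rate comparisons across
temperatures conflate locomotion costs with thermal physiology.  This
module estimates SMR (and activity-controlled metabolic rate) at each
temperature condition by three complementary approaches:

1. *Extrapolation* — fit MO2 = a * exp(b * activity) to every paired
   (activity, MO2) interval of a fish (or the pooled group) at one
   condition; the intercept ``a`` is the MO2 extrapolated to zero
   activity, i.e. SMR.  Fits whose activity effect is not significant
   (typically from too little activity spread) fall back to the
   lowest-20 method.
2. *Lowest-20 subsets* — mean of the 20 smallest MO2 values, or the MO2
   values at the 20 lowest activity levels.
3. *Activity-controlled MR* — mean MO2 within a narrow activity band that
   is occupied at every compared condition.

Routine metabolic rate (mean of all MO2, no activity control) is provided
for contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExponentialFit",
    "SmrEstimate",
    "fit_exponential",
    "smr_individual",
    "smr_group",
    "smr_lowest20_mo2",
    "smr_lowest20_activity",
    "activity_controlled_mr",
    "routine_mr",
    "estimate_all",
    "auto_band",
]

MIN_PAIRS_FOR_FIT = 5
LOWEST_N = 20


@dataclass(frozen=True)
class ExponentialFit:
    """Result of fitting MO2 = a * exp(b * activity)."""

    a: float          # intercept = SMR, mg O2 kg^-1 h^-1
    b: float          # slope per activity unit
    n: int
    r2: float
    p_value: float    # two-sided test of b = 0 (log-linear form)
    converged: bool


@dataclass(frozen=True)
class SmrEstimate:
    """SMR or activity-controlled MR for one fish/group at one condition."""

    scope: str        # fish_id or "group"
    condition: str
    temp_c: float
    method: str       # extrapolated_individual | extrapolated_group |
                      # lowest20_mo2 | lowest20_activity | overlap_band | routine
    value: float
    n: int
    provenance: str = ""


def fit_exponential(activity, mo2, min_spread: float = 1e-8) -> ExponentialFit:
    """Nonlinear least squares of MO2 on activity.

    Initial values come from the log-linear regression ln(MO2) ~ activity,
    which also supplies the significance test of the activity effect
    (two-sided test of slope = 0).  Returns ``converged=False`` — never an
    exception — for n < 5, activity spread below ``min_spread`` or
    optimizer failure.
    """
    x = np.asarray(activity, dtype=float)
    y = np.asarray(mo2, dtype=float)
    n = x.size
    if n < MIN_PAIRS_FOR_FIT or np.ptp(x) <= min_spread or np.any(y <= 0):
        return ExponentialFit(float("nan"), float("nan"), int(n),
                              float("nan"), float("nan"), False)
    lin = stats.linregress(x, np.log(y))
    a0, b0 = float(np.exp(lin.intercept)), float(lin.slope)
    try:
        popt, _ = optimize.curve_fit(lambda xx, a, b: a * np.exp(b * xx),
                                     x, y, p0=(a0, b0), maxfev=10000)
        a_hat, b_hat = float(popt[0]), float(popt[1])
    except (RuntimeError, ValueError):
        return ExponentialFit(float("nan"), float("nan"), int(n),
                              float("nan"), float("nan"), False)
    if not np.isfinite(a_hat) or a_hat <= 0:
        return ExponentialFit(a_hat, b_hat, int(n), float("nan"),
                              float("nan"), False)
    resid = y - a_hat * np.exp(b_hat * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    # a perfect log-linear fit has zero stderr; report p = 0 in that case
    p = float(lin.pvalue) if np.isfinite(lin.pvalue) else 0.0
    return ExponentialFit(a_hat, b_hat, int(n), r2, p, True)


def _one_condition(df: pd.DataFrame) -> tuple[str, float]:
    cond = df["condition"].iloc[0]
    return str(cond), float(df["temp_c"].iloc[0])


def smr_lowest20_mo2(pairs: pd.DataFrame, scope: str = "fish") -> SmrEstimate:
    """Mean of the 20 smallest MO2 values (all values when n < 20)."""
    cond, temp = _one_condition(pairs)
    vals = np.sort(pairs["mo2"].to_numpy(dtype=float))
    k = min(LOWEST_N, vals.size)
    note = "" if vals.size >= LOWEST_N else f"only {vals.size} values available"
    return SmrEstimate(scope, cond, temp, "lowest20_mo2",
                       float(vals[:k].mean()), int(k), note)


def smr_lowest20_activity(pairs: pd.DataFrame, scope: str = "fish") -> SmrEstimate:
    """Mean MO2 over the 20 lowest-activity pairs.

    Ties in activity break by lower MO2, then earlier interval index.
    """
    cond, temp = _one_condition(pairs)
    cols = ["activity", "mo2"] + (["interval_index"] if "interval_index" in pairs else [])
    ordered = pairs.sort_values(cols, kind="mergesort")
    k = min(LOWEST_N, len(ordered))
    note = "" if len(ordered) >= LOWEST_N else f"only {len(ordered)} values available"
    return SmrEstimate(scope, cond, temp, "lowest20_activity",
                       float(ordered["mo2"].iloc[:k].mean()), int(k), note)


def routine_mr(pairs: pd.DataFrame, scope: str = "fish") -> SmrEstimate:
    """Routine metabolic rate: mean of all MO2 at the condition."""
    cond, temp = _one_condition(pairs)
    return SmrEstimate(scope, cond, temp, "routine",
                       float(pairs["mo2"].mean()), int(len(pairs)))


def activity_controlled_mr(pairs: pd.DataFrame, band: tuple[float, float],
                           scope: str = "fish") -> SmrEstimate | None:
    """Mean MO2 within a narrow activity band (lo <= activity <= hi).

    Returns ``None`` with a logged diagnostic when the band is unoccupied
    at this condition.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    cond, temp = _one_condition(pairs)
    sel = pairs[(pairs["activity"] >= lo) & (pairs["activity"] <= hi)]
    if sel.empty:
        logger.warning("activity band [%g, %g] unoccupied at condition %s "
                       "(activity range %.3g-%.3g, n=%d)", lo, hi, cond,
                       pairs["activity"].min(), pairs["activity"].max(), len(pairs))
        return None
    return SmrEstimate(scope, cond, temp, "overlap_band",
                       float(sel["mo2"].mean()), int(len(sel)),
                       f"band [{lo:g}, {hi:g}]")


def smr_individual(pairs: pd.DataFrame, alpha: float = 0.05,
                   min_spread: float = 1e-8) -> list[SmrEstimate]:
    """Per-fish extrapolated SMR at each condition, with fallback.

    The extrapolated intercept is used when the fit converged and its
    activity effect is significant (p < alpha); otherwise the lowest-20
    MO2 estimate replaces it, with provenance recording the fallback.
    """
    out: list[SmrEstimate] = []
    for (fish, cond), grp in pairs.groupby(["fish_id", "condition"], sort=False):
        fit = fit_exponential(grp["activity"], grp["mo2"], min_spread=min_spread)
        if fit.converged and fit.p_value < alpha:
            out.append(SmrEstimate(str(fish), str(cond), float(grp["temp_c"].iloc[0]),
                                   "extrapolated_individual", fit.a, fit.n,
                                   f"b={fit.b:.4g}, p={fit.p_value:.3g}, r2={fit.r2:.3f}"))
        else:
            fb = smr_lowest20_mo2(grp, scope=str(fish))
            why = "fit not converged" if not fit.converged else f"p={fit.p_value:.3g} >= {alpha}"
            out.append(SmrEstimate(str(fish), str(cond), fb.temp_c,
                                   "extrapolated_individual", fb.value, fb.n,
                                   f"fallback lowest20_mo2 ({why})"))
    return out


def smr_group(pairs: pd.DataFrame, alpha: float = 0.05,
              min_spread: float = 1e-8) -> list[SmrEstimate]:
    """Pooled extrapolated SMR per condition across all fish."""
    out: list[SmrEstimate] = []
    for cond, grp in pairs.groupby("condition", sort=False):
        if grp["fish_id"].nunique() < 2:
            logger.warning("condition %s has < 2 fish; skipping group fit", cond)
            continue
        fit = fit_exponential(grp["activity"], grp["mo2"], min_spread=min_spread)
        if fit.converged:
            out.append(SmrEstimate("group", str(cond), float(grp["temp_c"].iloc[0]),
                                   "extrapolated_group", fit.a, fit.n,
                                   f"b={fit.b:.4g}, p={fit.p_value:.3g}"))
        else:
            fb = smr_lowest20_mo2(grp, scope="group")
            out.append(SmrEstimate("group", str(cond), fb.temp_c,
                                   "extrapolated_group", fb.value, fb.n,
                                   "fallback lowest20_mo2 (fit not converged)"))
    return out


def auto_band(pairs: pd.DataFrame, width: float | None = None,
              quantile: float = 0.8) -> tuple[float, float]:
    """Widest low-activity band occupied at every condition.

    Helper only — band choice is the caller's responsibility and this is
    never applied silently.  The band runs from the maximum over
    conditions of the per-condition minimum activity up to the minimum
    over conditions of the per-condition ``quantile`` activity (or
    ``lo + width`` when a width is given).
    """
    lo = float(pairs.groupby("condition")["activity"].min().max())
    if width is not None:
        return lo, lo + width
    hi = float(pairs.groupby("condition")["activity"].quantile(quantile).min())
    if hi <= lo:
        raise ValueError("no activity band is occupied at every condition")
    return lo, hi


def estimate_all(pairs: pd.DataFrame, band: tuple[float, float] | None = None,
                 alpha: float = 0.05) -> pd.DataFrame:
    """All estimators over a pairs table, as one tidy frame.

    Per fish x condition: extrapolated (with fallback), lowest-20 MO2,
    lowest-20 activity, routine and (when a band is given) overlap-band
    estimates; plus the pooled group extrapolation per condition.
    """
    ests: list[SmrEstimate] = []
    ests.extend(smr_individual(pairs, alpha=alpha))
    for (fish, _cond), grp in pairs.groupby(["fish_id", "condition"], sort=False):
        ests.append(smr_lowest20_mo2(grp, scope=str(fish)))
        ests.append(smr_lowest20_activity(grp, scope=str(fish)))
        ests.append(routine_mr(grp, scope=str(fish)))
        if band is not None:
            est = activity_controlled_mr(grp, band, scope=str(fish))
            if est is not None:
                ests.append(est)
    ests.extend(smr_group(pairs, alpha=alpha))
    return pd.DataFrame([e.__dict__ for e in ests])
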