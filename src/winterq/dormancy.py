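"""Dormancy threshold temperatures from behavioural tables.

A species' winter dormancy threshold is the temperature at which a
behaviour (activity, sheltering, vigilance or feeding) reaches a cold
steady state: further cooling no longer changes it significantly relative
to the coldest tested temperature.  Each fish serves as its own control —
per-temperature contrasts against the coldest temperature use within-fish
paired tests with Bonferroni adjustment across temperatures.  (The
comparison engine is pluggable: paired t by default, Wilcoxon signed-rank
for heavy-tailed metrics.)

Mean inactive / fasting temperatures complement the steady states: the
average temperature at which individual fish first reach — and then keep —
a zero level of the metric during monotone cooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SteadyStateResult",
    "TransitionResult",
    "detect_cold_steady_state",
    "mean_transition_temperature",
    "diel_contrast",
]


@dataclass
class SteadyStateResult:
    """Cold steady state of one metric/phase."""

    metric: str
    phase: str
    threshold_temp_c: float | None
    p_adjusted: pd.Series = field(repr=False)  # index: temp_c (non-coldest)
    n_fish: int = 0
    alpha: float = 0.05


@dataclass
class TransitionResult:
    """Mean temperature of entry into an inactive or fasting state."""

    metric: str
    mean_temp_c: float
    sem: float
    n_transitioned: int
    n_total: int
    population_transitioned: bool  # False when < half the fish transitioned

    @property
    def per_fish(self):  # filled by mean_transition_temperature
        return self._per_fish


def _paired_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    """Two-sided paired test on per-fish differences; p=1 for degenerate data."""
    d = a - b
    if np.allclose(d, d[0]):
        # zero-variance differences: identical (p=1) or a fixed offset (p=0)
        return 1.0 if np.isclose(d[0], 0.0) else 0.0
    if test == "t":
        res = stats.ttest_rel(a, b)
    elif test == "wilcoxon":
        res = stats.wilcoxon(a, b, zero_method="zsplit")
    else:
        raise ValueError(f"unknown paired test {test!r}")
    p = float(res.pvalue)
    return p if np.isfinite(p) else 1.0


def detect_cold_steady_state(values: pd.DataFrame, metric: str = "value",
                             phase: str = "day", alpha: float = 0.05,
                             test: str = "t") -> SteadyStateResult:
    """Warmest temperature from which the metric is at its cold steady state.

    ``values`` is a fish x temperature matrix (rows: fish, columns:
    temperatures in any order).  Every non-coldest temperature is compared
    against the coldest with a within-fish paired two-sided test,
    Bonferroni-adjusted across the m comparisons.  The threshold is the
    warmest temperature T* such that every tested temperature <= T* is
    non-significant (a contiguous non-significant run from the cold end);
    if even the second-coldest temperature differs significantly the
    steady state comprises only the coldest temperature, which is then
    reported as the threshold.
    """
    mat = values.dropna(axis=0, how="any")
    temps = sorted(float(c) for c in mat.columns)
    if len(temps) < 2:
        raise ValueError("need at least 2 temperatures")
    if len(mat) < 5:
        logger.warning("only %d fish with complete pairing; no steady-state result",
                       len(mat))
        return SteadyStateResult(metric, phase, None,
                                 pd.Series(dtype=float), len(mat), alpha)
    coldest = temps[0]
    tested = temps[1:]
    m = len(tested)
    ref = mat[_col(mat, coldest)].to_numpy(dtype=float)
    p_adj = {}
    for t in tested:
        p = _paired_p(mat[_col(mat, t)].to_numpy(dtype=float), ref, test)
        p_adj[t] = min(1.0, p * m)
    p_ser = pd.Series(p_adj).sort_index()
    threshold = coldest
    for t in tested:  # cold -> warm
        if p_ser[t] >= alpha:
            threshold = t
        else:
            break
    return SteadyStateResult(metric, phase, threshold, p_ser, len(mat), alpha)


def _col(df: pd.DataFrame, temp: float):
    """Resolve the column whose float value equals ``temp``."""
    for c in df.columns:
        if float(c) == temp:
            return c
    raise KeyError(temp)


def mean_transition_temperature(values: pd.DataFrame, metric: str = "activity",
                                zero_tol: float = 0.0) -> TransitionResult:
    """Mean temperature at which fish enter a persistent zero state.

    ``values`` is a fish x temperature matrix recorded during monotone
    cooling.  A fish's transition temperature is the warmest temperature
    at which the metric first reaches <= ``zero_tol`` and stays there at
    all colder tested temperatures.  Fish that never satisfy this count in
    ``n_total`` but not in the mean; when fewer than half transition the
    result is flagged as a population that did not transition.
    """
    temps = [float(c) for c in values.columns]
    order = np.argsort(temps)[::-1]  # warm -> cold
    temps_sorted = [temps[i] for i in order]
    if len(temps_sorted) != len(set(temps_sorted)):
        raise ValueError("duplicate temperatures")
    per_fish = {}
    for fish, row in values.iterrows():
        vals = row.to_numpy(dtype=float)[order]
        trans = None
        # scan cold -> warm while the metric stays at (or below) zero_tol
        for t, v in zip(temps_sorted[::-1], vals[::-1]):
            if v <= zero_tol:
                trans = t
            else:
                break
        if trans is not None:
            per_fish[fish] = trans
    n_total = len(values)
    n_trans = len(per_fish)
    ser = pd.Series(per_fish, dtype=float)
    mean = float(ser.mean()) if n_trans else float("nan")
    sem = float(ser.sem()) if n_trans > 1 else float("nan")
    res = TransitionResult(metric, mean, sem, n_trans, n_total,
                           population_transitioned=(n_trans / n_total >= 0.5 if n_total else False))
    res._per_fish = ser
    if not res.population_transitioned:
        logger.info("%s: population did not transition (%d/%d fish)",
                    metric, n_trans, n_total)
    return res


def diel_contrast(day: pd.DataFrame, night: pd.DataFrame,
                  test: str = "t") -> pd.Series:
    """Day-vs-night paired contrast at each temperature.

    ``day`` and ``night`` are fish x temperature matrices with identical
    indexing.  Returns Bonferroni-adjusted p-values indexed by
    temperature; temperatures missing a phase are skipped.
    """
    temps = [c for c in day.columns if c in set(night.columns)]
    m = len(temps)
    out = {}
    for t in temps:
        pair = pd.concat([day[t], night[t]], axis=1, keys=["d", "n"]).dropna()
        if pair.empty:
            continue
        p = _paired_p(pair["d"].to_numpy(float), pair["n"].to_numpy(float), test)
        out[float(t)] = min(1.0, p * m)
    return pd.Series(out).sort_index()
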