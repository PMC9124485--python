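"""Reduce intermittent-closed respirometry traces to oxygen uptake rates.

A trial alternates sealed (measurement) and flushed (re-oxygenation)
phases.  Within each closed period, oxygen declines approximately linearly
once the post-flush equilibration transient has passed; the slope of that
decline, corrected for background (blank) respiration and scaled by the
effective water volume and body mass, is the fish's mass-specific oxygen
uptake:

    MO2 = (blank_slope - raw_slope) * V_eff / mass   [mg O2 kg^-1 h^-1]

The first five minutes of every closed period (the equilibration period
following the flush) are excluded from the slope fit by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RespirometerGeometry",
    "CyclePlan",
    "Mo2Interval",
    "segment_cycles",
    "fit_slope",
    "blank_correct_and_scale",
    "match_blank",
    "extract_intervals",
    "process_trace",
]

#: minimum usable data beyond the equilibration exclusion, seconds
_MIN_FIT_SPAN_S = 120.0
#: minimum number of samples for a slope fit
_MIN_FIT_SAMPLES = 10


@dataclass(frozen=True)
class RespirometerGeometry:
    """Chamber volume, body mass and the derived effective water volume."""

    chamber_volume_l: float
    body_mass_kg: float
    body_volume_l: float | None = None  # defaults to mass at density 1 kg/L

    def __post_init__(self):
        if self.body_mass_kg <= 0:
            raise ValueError("body_mass_kg must be > 0")
        if self.chamber_volume_l <= 0:
            raise ValueError("chamber_volume_l must be > 0")
        if self.effective_volume_l <= 0:
            raise ValueError("effective volume must be > 0 (fish larger than chamber?)")

    @property
    def effective_volume_l(self) -> float:
        body = self.body_volume_l if self.body_volume_l is not None else self.body_mass_kg / 1.0
        return self.chamber_volume_l - body


@dataclass(frozen=True)
class CyclePlan:
    """Timing of the intermittent cycle.

    ``equilibration_exclusion_s`` samples at the start of each closed
    period are dropped before the slope fit (default 300 s).
    """

    closed_duration_s: float
    flush_duration_s: float
    equilibration_exclusion_s: float = 300.0

    def __post_init__(self):
        if self.closed_duration_s <= self.equilibration_exclusion_s:
            raise ValueError("closed_duration_s must exceed equilibration_exclusion_s")
        if self.flush_duration_s < 0:
            raise ValueError("flush_duration_s must be >= 0")


@dataclass
class Mo2Interval:
    """One closed-period measurement."""

    chamber_id: str
    interval_index: int
    start_s: float
    end_s: float
    mean_temp_c: float
    raw_slope: float          # mg O2 L^-1 h^-1, <= 0 expected
    r2: float
    n_samples: int
    blank_slope: float = 0.0
    mo2: float = float("nan")  # mg O2 kg^-1 h^-1
    qc_pass: bool = False
    qc_note: str = ""

    @property
    def mid_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def segment_cycles(trace: pd.DataFrame, plan: CyclePlan,
                   t0_s: float = 0.0) -> list[tuple[float, float]]:
    """Closed-period windows ``[start, end)`` implied by the cycle plan.

    Windows start at ``t0_s + k * (closed + flush)`` and are truncated to
    the trace extent; windows too short to fit after the equilibration
    exclusion are dropped with a logged reason.
    """
    if trace.empty:
        raise ValueError("empty oxygen trace")
    t_end = float(trace["time_s"].iloc[-1])
    period = plan.closed_duration_s + plan.flush_duration_s
    windows: list[tuple[float, float]] = []
    k = 0
    while True:
        start = t0_s + k * period
        if start >= t_end:
            break
        next_start = t0_s + (k + 1) * period
        # cap at the next cycle start: guards float jitter when flush ~ 0
        end = min(start + plan.closed_duration_s, next_start, t_end)
        if end - start >= plan.equilibration_exclusion_s + _MIN_FIT_SPAN_S:
            windows.append((start, end))
        else:
            logger.warning("dropping closed window [%g, %g): only %g s usable",
                           start, end, end - start)
        k += 1
    if not windows:
        logger.warning("trace shorter than one usable closed period")
    return windows


def fit_slope(time_s: np.ndarray, o2_mg_per_l: np.ndarray,
              exclusion_s: float = 300.0) -> tuple[float, float, int]:
    """OLS slope of oxygen vs time within one closed window.

    Samples within ``exclusion_s`` of the window start are dropped.  Times
    are rescaled to hours so the slope is in mg O2 L^-1 h^-1.  Returns
    ``(slope, r2, n_used)``; ``(nan, nan, n)`` when fewer than 10 samples
    remain (the caller flags the interval instead of raising).
    """
    time_s = np.asarray(time_s, dtype=float)
    o2 = np.asarray(o2_mg_per_l, dtype=float)
    keep = time_s >= time_s[0] + exclusion_s
    t, y = time_s[keep], o2[keep]
    if t.size < _MIN_FIT_SAMPLES:
        return float("nan"), float("nan"), int(t.size)
    res = stats.linregress(t / 3600.0, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return float(res.slope), r2, int(t.size)


def blank_correct_and_scale(raw_slope: float, blank_slope: float,
                            geometry: RespirometerGeometry) -> tuple[float, bool]:
    """Blank-corrected, mass-specific oxygen uptake.

    ``mo2 = (blank_slope - raw_slope) * V_eff / mass``.  A negative result
    (fish apparently producing oxygen) is returned with ``qc_pass=False``
    rather than clamped, to keep QC visible.
    """
    mo2 = (blank_slope - raw_slope) * geometry.effective_volume_l / geometry.body_mass_kg
    return mo2, mo2 >= 0.0


def match_blank(intervals: list[Mo2Interval],
                blank_intervals: list[Mo2Interval]) -> list[Mo2Interval]:
    """Fill each interval's blank slope from the temporally nearest blank.

    Ties in |delta t| go to the earlier blank.  With no blanks available,
    blank_slope stays 0 and a warning is logged.
    """
    if not blank_intervals:
        logger.warning("no blank intervals available; background assumed zero")
        return intervals
    blanks = sorted(blank_intervals, key=lambda b: b.mid_s)
    for iv in intervals:
        best = min(blanks, key=lambda b: (abs(b.mid_s - iv.mid_s), b.mid_s))
        iv.blank_slope = best.raw_slope
    return intervals


def extract_intervals(trace: pd.DataFrame, plan: CyclePlan,
                      chamber_id: str | None = None,
                      t0_s: float = 0.0) -> list[Mo2Interval]:
    """Slope-fit every closed window of a raw trace (no blank correction yet)."""
    if chamber_id is None:
        chamber_id = str(trace["chamber_id"].iloc[0]) if "chamber_id" in trace else "?"
    out = []
    for idx, (start, end) in enumerate(segment_cycles(trace, plan, t0_s)):
        m = (trace["time_s"] >= start) & (trace["time_s"] < end)
        win = trace.loc[m]
        slope, r2, n = fit_slope(win["time_s"].to_numpy(),
                                 win["o2_mg_per_l"].to_numpy(),
                                 plan.equilibration_exclusion_s)
        iv = Mo2Interval(chamber_id, idx, start, end,
                         float(win["temp_c"].mean()) if "temp_c" in win else float("nan"),
                         slope, r2, n)
        if not np.isfinite(slope):
            iv.qc_note = f"too few samples after exclusion (n={n})"
        out.append(iv)
    return out


def process_trace(trace: pd.DataFrame, plan: CyclePlan,
                  geometry: RespirometerGeometry,
                  blank_trace: pd.DataFrame | None = None,
                  min_r2: float = 0.9,
                  t0_s: float = 0.0) -> list[Mo2Interval]:
    """Full reduction: segment, fit, blank-correct and QC one chamber.

    ``min_r2`` is an acceptance floor on the slope fit's coefficient of
    determination (an assumption of this package; configurable).  Constant
    traces (slope ~ 0, r2 undefined) are accepted.
    """
    intervals = extract_intervals(trace, plan, t0_s=t0_s)
    if blank_trace is not None:
        blanks = extract_intervals(blank_trace, plan, chamber_id="blank", t0_s=t0_s)
        blanks = [b for b in blanks if np.isfinite(b.raw_slope)]
        match_blank(intervals, blanks)
    for iv in intervals:
        if not np.isfinite(iv.raw_slope):
            iv.qc_pass = False
            continue
        mo2, ok = blank_correct_and_scale(iv.raw_slope, iv.blank_slope, geometry)
        iv.mo2 = mo2
        flat = abs(iv.raw_slope) < 1e-9
        iv.qc_pass = ok and (flat or iv.r2 >= min_r2)
        if not ok:
            iv.qc_note = "negative MO2 after blank correction"
        elif not iv.qc_pass:
            iv.qc_note = f"r2 {iv.r2:.3f} below {min_r2}"
    return intervals


def intervals_to_frame(intervals: list[Mo2Interval]) -> pd.DataFrame:
    """Tidy table of interval results."""
    return pd.DataFrame([{
        "chamber_id": iv.chamber_id, "interval_index": iv.interval_index,
        "start_s": iv.start_s, "end_s": iv.end_s, "mean_temp_c": iv.mean_temp_c,
        "raw_slope": iv.raw_slope, "r2": iv.r2, "n_samples": iv.n_samples,
        "blank_slope": iv.blank_slope, "mo2": iv.mo2,
        "qc_pass": iv.qc_pass, "qc_note": iv.qc_note,
    } for iv in intervals])
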