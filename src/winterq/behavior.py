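"""Per-fish, per-temperature, per-diel-phase behavioural metrics.

Reduces tracked-movement summaries, visibility (sheltering), vigilance
scores and feeding counts into tidy activity summaries.  Activity is the
size-standardized average speed in body lengths per minute (BL min^-1):
total distance moved over the phase divided by the phase duration and the
fish's total length.  Sheltering is the fraction of time the tracker could
not see the fish (inside its opaque shelter, where activity is taken to be
zero).  Vigilance is the mean of ordinal scores in {0, 0.5, 1} (hidden /
head out / fully out).  Feeding is the fraction of the offered ration
consumed over 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time as dtime

import numpy as np
import pandas as pd

__all__ = [
    "TrackSummary",
    "compute_activity",
    "apply_inactive_control",
    "compute_sheltering",
    "score_vigilance",
    "compute_feeding",
    "clip_phase_window",
    "mean_daily_temperature",
    "DAY_WINDOW",
    "NIGHT_WINDOW",
]

#: measurement clock windows, half-open [start, end); night wraps midnight
DAY_WINDOW = (dtime(9, 0), dtime(16, 0))
NIGHT_WINDOW = (dtime(19, 0), dtime(6, 0))

VIGILANCE_SCORES = frozenset({0.0, 0.5, 1.0})


@dataclass(frozen=True)
class TrackSummary:
    """Raw tracker output for one fish over one phase at one temperature."""

    fish_id: str
    phase: str               # "day" | "night"
    temp_c: float
    total_distance_px: float
    calibration_cm_per_px: float
    duration_min: float
    invisible_time_min: float = 0.0

    def __post_init__(self):
        if self.total_distance_px < 0:
            raise ValueError("distance must be >= 0")
        if self.invisible_time_min > self.duration_min:
            raise ValueError("invisible time cannot exceed duration")


def compute_activity(track: TrackSummary, total_length_cm: float) -> float:
    """Activity in BL min^-1: (distance_px * cm/px / TL_cm) / duration_min."""
    if track.duration_min <= 0:
        raise ValueError("duration must be > 0")
    if total_length_cm <= 0:
        raise ValueError("total_length_cm must be > 0")
    bl = track.total_distance_px * track.calibration_cm_per_px / total_length_cm
    return bl / track.duration_min


def apply_inactive_control(activity: float, control_value: float) -> float:
    """Subtract the fish's tracker-noise floor, flooring at zero.

    ``control_value`` is the mean apparent movement over several (>= 3)
    visually confirmed inactive periods; subtracting it removes postural
    adjustments and flow buffeting from the activity estimate.
    """
    if control_value < 0:
        raise ValueError("control_value must be >= 0")
    return max(activity - control_value, 0.0)


def compute_sheltering(track: TrackSummary) -> float:
    """Fraction of the phase the fish was invisible to the tracker."""
    if track.duration_min <= 0:
        raise ValueError("duration must be > 0")
    return track.invisible_time_min / track.duration_min


def score_vigilance(scores) -> float:
    """Mean of per-observation vigilance scores; NaN for no observations."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        return float("nan")
    bad = set(np.unique(arr)) - VIGILANCE_SCORES
    if bad:
        raise ValueError(f"vigilance scores must be in {{0, 0.5, 1}}; got {sorted(bad)}")
    return float(arr.mean())


def compute_feeding(ration_count: int, remaining_count: int) -> float:
    """Fraction of the offered ration consumed: (offered - remaining)/offered."""
    if ration_count <= 0:
        raise ValueError("ration_count must be > 0")
    if not 0 <= remaining_count <= ration_count:
        raise ValueError("remaining_count must be within [0, ration_count]")
    return (ration_count - remaining_count) / ration_count


def _in_window(t: dtime, window: tuple[dtime, dtime]) -> bool:
    start, end = window
    if start <= end:
        return start <= t < end
    return t >= start or t < end  # wraps midnight


def clip_phase_window(samples: pd.DataFrame, phase: str,
                      time_col: str = "clock_time") -> pd.DataFrame:
    """Keep samples inside the day (09:00-16:00) or night (19:00-06:00) window.

    Windows are half-open so a sample at exactly the end boundary is
    excluded and no sample can belong to both phases.
    """
    window = {"day": DAY_WINDOW, "night": NIGHT_WINDOW}[phase]
    times = samples[time_col]
    mask = times.map(lambda t: _in_window(t if isinstance(t, dtime) else t.time(), window))
    return samples.loc[mask]


def mean_daily_temperature(morning_c: float, evening_c: float,
                           daily_min_c: float, daily_max_c: float) -> float:
    """Mean of the morning, evening, minimum and maximum readings."""
    if daily_min_c > daily_max_c:
        raise ValueError("daily_min_c must be <= daily_max_c")
    return (morning_c + evening_c + daily_min_c + daily_max_c) / 4.0
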