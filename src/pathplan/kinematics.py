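"""Gait-speed measures and start-foot summaries from trajectory samples.

Gait speed is anterior-posterior (forward, +y) ankle displacement divided
by elapsed time; lateral excursions of the path never enter.  The
``to_margin`` segment ends at the obstacle's longitudinal midline (front
face plus half the depth).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .layout import LayoutError, WalkwayLayout
from .models import start_foot_choice_correlation
from .simulate import Trial

__all__ = ["gait_speed", "speed_summary", "start_foot_summary"]

_ANKLE_STREAMS = ("ankle_left", "ankle_right")


def _ankle_speed(traj: pd.DataFrame, stream: str, y_stop: float | None) -> float:
    sub = traj[traj["stream"] == stream].sort_values("t_s")
    if len(sub) < 2:
        raise ValueError(f"need >= 2 samples in stream {stream!r}")
    t = sub["t_s"].to_numpy(dtype=float)
    y = sub["y_cm"].to_numpy(dtype=float)
    if y_stop is None:
        elapsed = t[-1] - t[0]
        if elapsed <= 0:
            raise ValueError("zero elapsed time")
        return (y[-1] - y[0]) / elapsed
    crossed = np.flatnonzero(y >= y_stop)
    if crossed.size == 0:
        raise ValueError("trajectory never reaches the margin midline")
    i = int(crossed[0])
    if i == 0:
        raise ValueError("trajectory starts beyond the margin midline")
    # linear interpolation of the crossing time
    frac = (y_stop - y[i - 1]) / (y[i] - y[i - 1])
    t_cross = t[i - 1] + frac * (t[i] - t[i - 1])
    elapsed = t_cross - t[0]
    if elapsed <= 0:
        raise ValueError("zero elapsed time")
    return (y_stop - y[0]) / elapsed


def gait_speed(
    trial: Trial, segment: str = "full", layout: WalkwayLayout | None = None
) -> float:
    """Average gait speed (cm/s) over the full path or up to the obstacle.

    ``segment="to_margin"`` requires the trial's layout and an obstacle;
    speeds are averaged over the two ankle streams.
    """
    if segment == "full":
        y_stop = None
    elif segment == "to_margin":
        if layout is None:
            raise ValueError("to_margin segment requires the layout")
        if not layout.has_obstacle:
            raise LayoutError("to_margin speed undefined without an obstacle")
        y_stop = layout.obstacle_distance + layout.obstacle_depth / 2.0
    else:
        raise ValueError(f"unknown segment {segment!r}")
    speeds = [_ankle_speed(trial.trajectory, s, y_stop) for s in _ANKLE_STREAMS]
    return float(np.mean(speeds))


def speed_summary(
    trials: Iterable[Trial], layouts: Mapping[int, WalkwayLayout]
) -> pd.DataFrame:
    """Mean and SE of full/to-margin speeds per condition x target."""
    rows = []
    for trial in trials:
        layout = layouts[trial.condition_id]
        entry = {
            "condition": trial.condition_id,
            "target_offset_cm": trial.target_offset_cm,
            "speed_full": gait_speed(trial, "full"),
        }
        entry["speed_to_margin"] = (
            gait_speed(trial, "to_margin", layout) if layout.has_obstacle else np.nan
        )
        rows.append(entry)
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["condition", "target_offset_cm"])
        .agg(
            speed_full_mean=("speed_full", "mean"),
            speed_full_se=("speed_full", "sem"),
            speed_to_margin_mean=("speed_to_margin", "mean"),
            speed_to_margin_se=("speed_to_margin", "sem"),
            n=("speed_full", "size"),
        )
        .reset_index()
    )
    return out


def start_foot_summary(trials: Iterable[Trial]) -> tuple[pd.DataFrame, float, float]:
    """Right-foot start frequency (%) per condition x target, plus the
    Pearson correlation (and p) between start foot and chosen side.

    The correlation is NaN when either indicator is constant.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    df = pd.DataFrame(
        {
            "condition": [t.condition_id for t in trials],
            "target_offset_cm": [t.target_offset_cm for t in trials],
            "right_foot": [t.start_foot == "right" for t in trials],
        }
    )
    table = (
        df.groupby(["target_offset_cm", "condition"])["right_foot"]
        .mean()
        .mul(100.0)
        .unstack("condition")
    )
    r, p = start_foot_choice_correlation(
        [t.start_foot for t in trials], [t.chosen_side for t in trials]
    )
    return table, r, p
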