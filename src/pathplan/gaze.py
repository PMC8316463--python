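"""AOI construction, gaze labeling, dwell/allocation statistics, and AMGR.

Gaze samples are ground-plane points (cm) in the layout frame.  Four labels
are produced: ``T`` (target zone), ``S_left``/``S_right`` (avoidance-margin
strips spanning the obstacle depth), ``P`` (remaining walkway), and ``none``
for everything else.  Labeling is by priority T > margins > P, which keeps
the effective regions disjoint.

AMGR contrasts margin dwell times::

    amgr = (dwell_right - dwell_left) / (dwell_right + dwell_left)

and is NaN when no margin gaze exists (callers must filter before
regression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import KernelDensity

from .layout import BOOKCASE_DEPTH, LayoutError, WalkwayLayout, avoidance_margins

__all__ = [
    "Rect",
    "AoiRegions",
    "GridSpec",
    "label_aoi",
    "label_points",
    "sample_dwells",
    "dwell_times",
    "amgr",
    "allocation_map",
    "gaze_frequency",
    "ray_ground_intersection",
]

#: Nominal eye-tracker sampling interval (120 Hz).
NOMINAL_DT = 1.0 / 120.0

#: Gaps longer than this many nominal intervals are not bridged as dwell.
MAX_GAP_INTERVALS = 3


@dataclass(frozen=True)
class Rect:
    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax

    def contains_array(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)


@dataclass(frozen=True)
class AoiRegions:
    """Ground-plane areas of interest derived from a layout."""

    target: Rect
    walkway: Rect
    am_left: Rect | None = None
    am_right: Rect | None = None

    @property
    def has_margins(self) -> bool:
        return self.am_left is not None and self.am_right is not None

    @classmethod
    def from_layout(
        cls,
        layout: WalkwayLayout,
        target_halo: float = 10.0,
        margin_pad: float = 20.0,
    ) -> "AoiRegions":
        """Build AOIs: target zone = bookcase footprint plus a halo; margin
        strips span the obstacle depth plus ``margin_pad`` on each end."""
        half_w = layout.walkway_width / 2.0
        target = Rect(
            -layout.bookcase_width / 2.0 - target_halo,
            layout.bookcase_width / 2.0 + target_halo,
            layout.walkway_length - target_halo,
            layout.walkway_length + BOOKCASE_DEPTH + target_halo,
        )
        walkway = Rect(-half_w, half_w, 0.0, layout.walkway_length)
        if not layout.has_obstacle:
            return cls(target=target, walkway=walkway)
        left_edge, right_edge = layout.obstacle_edges
        y0 = layout.obstacle_distance - margin_pad
        y1 = layout.obstacle_distance + layout.obstacle_depth + margin_pad
        return cls(
            target=target,
            walkway=walkway,
            am_left=Rect(-half_w, left_edge, y0, y1),
            am_right=Rect(right_edge, half_w, y0, y1),
        )


def label_aoi(point: tuple[float, float], regions: AoiRegions) -> str:
    """Label one ground-plane point: T, S_left, S_right, P, or none."""
    x, y = point
    if regions.target.contains(x, y):
        return "T"
    if regions.am_left is not None and regions.am_left.contains(x, y):
        return "S_left"
    if regions.am_right is not None and regions.am_right.contains(x, y):
        return "S_right"
    if regions.walkway.contains(x, y):
        return "P"
    return "none"


def label_points(x: np.ndarray, y: np.ndarray, regions: AoiRegions) -> np.ndarray:
    """Vectorized :func:`label_aoi` over coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(x.shape, "none", dtype=object)
    in_walkway = regions.walkway.contains_array(x, y)
    out[in_walkway] = "P"
    if regions.am_left is not None:
        out[regions.am_left.contains_array(x, y)] = "S_left"
    if regions.am_right is not None:
        out[regions.am_right.contains_array(x, y)] = "S_right"
    out[regions.target.contains_array(x, y)] = "T"
    return out


def sample_dwells(
    t: np.ndarray,
    nominal_dt: float = NOMINAL_DT,
    max_gap_intervals: int = MAX_GAP_INTERVALS,
) -> np.ndarray:
    """Dwell (s) credited to each sample: the interval to the next sample,
    capped so long recording gaps are not bridged; the last sample gets the
    nominal interval."""
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        return np.zeros(0)
    dwell = np.full(t.size, nominal_dt)
    if t.size > 1:
        gaps = np.diff(t)
        dwell[:-1] = np.minimum(gaps, max_gap_intervals * nominal_dt)
    return dwell


def dwell_times(
    gaze: pd.DataFrame, regions: AoiRegions, nominal_dt: float = NOMINAL_DT
) -> dict[str, float]:
    """Total dwell seconds per AOI token for one trial's gaze frame
    (columns ``t_s``, ``x_cm``, ``y_cm``)."""
    labels = label_points(gaze["x_cm"].to_numpy(), gaze["y_cm"].to_numpy(), regions)
    dwell = sample_dwells(gaze["t_s"].to_numpy(), nominal_dt)
    out = {tok: 0.0 for tok in ("T", "P", "S_left", "S_right", "none")}
    for tok in out:
        out[tok] = float(dwell[labels == tok].sum())
    return out


def amgr(gaze: pd.DataFrame, regions: AoiRegions) -> float:
    """Avoidance-margin gaze ratio in [-1, +1]; NaN when no margin dwell.

    Raises :class:`LayoutError` for regions without margins (no-obstacle).
    """
    if not regions.has_margins:
        raise LayoutError("AMGR undefined without avoidance-margin AOIs")
    d = dwell_times(gaze, regions)
    total = d["S_left"] + d["S_right"]
    if total <= 0:
        return float("nan")
    return (d["S_right"] - d["S_left"]) / total


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grid for allocation maps."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    nx: int = 40
    ny: int = 120

    @classmethod
    def from_layout(cls, layout: WalkwayLayout, nx: int = 40, ny: int = 120) -> "GridSpec":
        half = layout.walkway_width / 2.0
        return cls(-half, half, 0.0, layout.walkway_length + BOOKCASE_DEPTH, nx, ny)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        xs = np.linspace(self.xmin, self.xmax, self.nx)
        ys = np.linspace(self.ymin, self.ymax, self.ny)
        return np.meshgrid(xs, ys)


def allocation_map(
    gaze: pd.DataFrame,
    regions: AoiRegions,
    grid: GridSpec,
    bandwidth: float = 15.0,
    duration_s: float | None = None,
    rescale: bool = True,
) -> np.ndarray:
    """Dwell-weighted Gaussian density of in-AOI gaze on a ground-plane grid,
    normalized by trial duration, then affinely rescaled to [0, 10]
    (``rescale=False`` returns the raw intensity).

    Returns an (ny, nx) array.  Raises ``ValueError`` on an empty gaze
    stream; a stream with no in-AOI samples yields an all-zero map.
    """
    if len(gaze) == 0:
        raise ValueError("empty gaze stream")
    t = gaze["t_s"].to_numpy()
    x = gaze["x_cm"].to_numpy()
    y = gaze["y_cm"].to_numpy()
    labels = label_points(x, y, regions)
    keep = labels != "none"
    gx, gy = grid.mesh()
    if not keep.any():
        return np.zeros(gx.shape)
    dwell = sample_dwells(t)[keep]
    if duration_s is None:
        duration_s = max(float(t[-1] - t[0]), NOMINAL_DT)
    kde = KernelDensity(bandwidth=bandwidth, kernel="gaussian")
    kde.fit(np.column_stack([x[keep], y[keep]]), sample_weight=dwell)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    density = np.exp(kde.score_samples(pts)).reshape(gx.shape)
    intensity = density * dwell.sum() / duration_s
    if not rescale:
        return intensity
    lo, hi = intensity.min(), intensity.max()
    if hi <= lo:
        return np.zeros(gx.shape)
    return 10.0 * (intensity - lo) / (hi - lo)


def gaze_frequency(
    trials: Iterable,
    regions_by_condition: Mapping[int, AoiRegions],
    merge_margins: bool = False,
) -> pd.DataFrame:
    """Long-format gaze sample counts per AOI x condition x target.

    ``trials`` yields objects with ``condition_id``, ``target_offset_cm``,
    and a ``gaze`` frame.  Counts are raw sample counts (not discrete gaze
    events).  With ``merge_margins`` the two margin AOIs are summed into a
    single ``S`` row; margin rows are structurally absent for conditions
    without margins.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    acc: dict[tuple[int, float, str], int] = {}
    for trial in trials:
        regions = regions_by_condition[trial.condition_id]
        labels = label_points(
            trial.gaze["x_cm"].to_numpy(), trial.gaze["y_cm"].to_numpy(), regions
        )
        tokens = ["T", "P"] + (["S_left", "S_right"] if regions.has_margins else [])
        for tok in tokens:
            key_tok = "S" if (merge_margins and tok.startswith("S_")) else tok
            key = (trial.condition_id, trial.target_offset_cm, key_tok)
            acc[key] = acc.get(key, 0) + int((labels == tok).sum())
    rows = [
        {"condition": c, "target_offset_cm": t, "aoi": a, "count": n}
        for (c, t, a), n in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def ray_ground_intersection(
    origin: Sequence[float], direction: Sequence[float]
) -> tuple[float, float]:
    """Intersect a 3-D gaze ray (x, y, z; z up) with the ground plane z = 0.

    Helper for callers holding (origin, direction) gaze vectors instead of
    pre-projected ground points.  Raises ``ValueError`` for rays parallel to
    or pointing away from the ground.
    """
    ox, oy, oz = (float(v) for v in origin)
    dx, dy, dz = (float(v) for v in direction)
    if dz == 0 or oz / -dz < 0:
        raise ValueError("gaze ray does not intersect the ground plane")
    s = oz / -dz
    return (ox + s * dx, oy + s * dy)
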