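"""Synthetic walking/gaze trials with the statistical structure the
downstream analyses assume.

The generator inverts the analysis models: path choice is Bernoulli under a
logistic model on the geometry features, gaze is a phase-structured
categorical stream over the AOIs, gait slows as the traversed margin
shrinks, and judgment ratings follow a logistic psychometric curve.
Everything is reproducible from a single root seed via deterministic
``SeedSequence`` substreams.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import layout as lay
from .gaze import NOMINAL_DT, AoiRegions
from .layout import GeometryFeatures, TargetPosition, WalkwayLayout

__all__ = [
    "ChoiceCoefficients",
    "GazePhase",
    "SimParams",
    "Trial",
    "choice_probability",
    "simulate_choice",
    "simulate_trajectory",
    "simulate_gaze",
    "simulate_judgment",
    "generate_dataset",
    "trials_to_frames",
    "trials_from_frames",
    "univariate_intercept",
]

RIGHT, LEFT = "right", "left"


@dataclass(frozen=True)
class ChoiceCoefficients:
    """Logit-scale weights of the generating choice model.

    The linear predictor is evaluated on centered features so the intercept
    is the neutral-geometry log-odds::

        eta = intercept + b_theta*dtheta + b_d*dd + b_amr*(amr - 1)
              + b_theta_d*dtheta*dd + b_theta_amr*dtheta*(amr - 1)

    The default intercept puts P(right) = 0.90 at neutral geometry
    (dtheta = 0, dd = 0, amr = 1).  The default angle weight is calibrated
    so P(right) reaches ~1 by dtheta = -5 deg, matching the observed
    right-side saturation; the reported univariate angle coefficient (-0.34)
    is shallower and is used explicitly in recovery tests instead.
    """

    intercept: float = float(logit(0.90))
    delta_theta: float = -0.50
    delta_d: float = -0.35
    amr: float = 4.67
    theta_x_d: float = 0.0
    theta_x_amr: float = 0.0

    def linear_predictor(self, features: GeometryFeatures) -> float:
        if not features.has_obstacle:
            raise ValueError("choice model requires obstacle features")
        dt, dd, am = features.delta_theta, features.delta_d, features.amr - 1.0
        eta = (
            self.intercept
            + self.delta_theta * dt
            + self.delta_d * dd
            + self.amr * am
            + self.theta_x_d * dt * dd
            + self.theta_x_amr * dt * am
        )
        if not math.isfinite(eta):
            raise ValueError("non-finite linear predictor")
        return eta

    def scaled(self, factors: np.ndarray) -> "ChoiceCoefficients":
        """Per-participant multiplicative jitter on the slope terms."""
        return ChoiceCoefficients(
            intercept=self.intercept,
            delta_theta=self.delta_theta * factors[0],
            delta_d=self.delta_d * factors[1],
            amr=self.amr * factors[2],
            theta_x_d=self.theta_x_d * factors[3],
            theta_x_amr=self.theta_x_amr * factors[4],
        )


def univariate_intercept(coef: float, anchor_value: float, anchor_p: float) -> float:
    """Intercept making a one-feature logistic model pass through
    ``P(right) = anchor_p`` at ``feature = anchor_value``."""
    return float(logit(anchor_p)) - coef * anchor_value


@dataclass(frozen=True)
class GazePhase:
    """One phase of the gaze stream: active until ``end`` (fraction of trial
    duration), with categorical AOI probabilities."""

    end: float
    probs: dict[str, float]  # keys: T, P, S, none


def default_phase_model() -> tuple[GazePhase, ...]:
    """Phase-structured gaze: early target+margin scanning, mid-trial margin
    emphasis, target-dominant after the obstacle, target-only at the end."""
    return (
        GazePhase(0.10, {"T": 0.50, "S": 0.35, "P": 0.10, "none": 0.05}),
        GazePhase(0.45, {"T": 0.30, "S": 0.50, "P": 0.15, "none": 0.05}),
        GazePhase(0.80, {"T": 0.60, "S": 0.10, "P": 0.25, "none": 0.05}),
        GazePhase(1.00, {"T": 0.90, "S": 0.01, "P": 0.03, "none": 0.06}),
    )


@dataclass
class SimParams:
    """Generator parameters; defaults emulate the study's reported structure."""

    choice: ChoiceCoefficients = field(default_factory=ChoiceCoefficients)
    gaze_phases: tuple[GazePhase, ...] = field(default_factory=default_phase_model)
    margin_gaze_choice_bias: float = 0.75  # P(margin gaze lands on chosen side)
    margin_attention_ref: float = 80.0  # cm; margins below this draw extra gaze
    speed_base: float = 130.0  # cm/s
    speed_margin_slowdown: float = 0.8  # cm/s per cm of margin deficit
    margin_comfort: float = 80.0  # cm; deficit = max(0, comfort - margin)
    trajectory_rate: float = 30.0  # Hz
    gaze_rate: float = 1.0 / NOMINAL_DT  # Hz
    trajectory_jitter_sd: float = 1.0  # cm
    judgment_threshold: float = -15.0  # cm (+ = right of shelf center)
    judgment_slope: float = 0.3  # logit per cm
    judgment_noise_sd: float = 0.5  # rating units
    start_foot_p_right: dict[float, float] = field(
        default_factory=lambda: {-30.0: 0.52, 0.0: 0.65, 30.0: 0.65}
    )
    start_foot_side_pull: float = 0.15  # shift toward the chosen side
    participant_jitter: float = 0.10  # +-10% multiplicative on slopes
    n_participants: int = 12
    n_trials_per_cell: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        ends = [p.end for p in self.gaze_phases]
        if ends != sorted(ends) or len(set(ends)) != len(ends):
            raise ValueError("gaze phase boundaries must be strictly increasing")
        if not 0 < ends[-1] <= 1.0:
            raise ValueError("last gaze phase must end at a fraction <= 1")
        for phase in self.gaze_phases:
            if abs(sum(phase.probs.values()) - 1.0) > 1e-9:
                raise ValueError("phase probabilities must sum to 1")
        if self.n_participants < 1 or self.n_trials_per_cell < 1:
            raise ValueError("n_participants and n_trials_per_cell must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gaze_phases"] = [dataclasses.asdict(p) for p in self.gaze_phases]
        return d


@dataclass
class Trial:
    """One synthetic walk: metadata plus trajectory and gaze sample frames."""

    trial_id: str
    participant_id: int
    condition_id: int
    target_offset_cm: float
    chosen_side: str
    start_foot: str
    duration_s: float
    trajectory: pd.DataFrame  # columns: t_s, x_cm, y_cm, stream
    gaze: pd.DataFrame  # columns: t_s, x_cm, y_cm


def choice_probability(features: GeometryFeatures, coef: ChoiceCoefficients) -> float:
    """P(choose the right side) under the generating logistic model."""
    return float(expit(coef.linear_predictor(features)))


def simulate_choice(
    features: GeometryFeatures, coef: ChoiceCoefficients, rng: np.random.Generator
) -> str:
    return RIGHT if rng.random() < choice_probability(features, coef) else LEFT


def _margin_midpoints(layout: WalkwayLayout) -> dict[str, float]:
    left_edge, right_edge = layout.obstacle_edges
    half = layout.walkway_width / 2.0
    return {LEFT: (-half + left_edge) / 2.0, RIGHT: (right_edge + half) / 2.0}


def simulate_trajectory(
    layout: WalkwayLayout,
    side: str | None,
    params: SimParams,
    rng: np.random.Generator,
    target: TargetPosition | None = None,
) -> pd.DataFrame:
    """Piecewise path through the chosen margin with margin-dependent slowing.

    Returns a long frame with streams ``body``, ``ankle_left``,
    ``ankle_right``.  ``side`` is ignored (may be None) for no-obstacle
    layouts, which produce a straight path.
    """
    target = target or TargetPosition(0.0)
    tx, ty = target.point(layout)
    if layout.has_obstacle:
        if side not in (LEFT, RIGHT):
            raise ValueError(f"side must be left/right, got {side!r}")
        am_left, am_right = lay.avoidance_margins(layout)
        margin = am_left if side == LEFT else am_right
        if margin <= 0:
            raise ValueError("infeasible side: margin not positive")
        mid_y = layout.obstacle_distance + layout.obstacle_depth / 2.0
        waypoints = [(0.0, 0.0), (_margin_midpoints(layout)[side], mid_y), (tx, ty)]
        deficit = max(0.0, params.margin_comfort - margin)
    else:
        waypoints = [(0.0, 0.0), (tx, ty)]
        deficit = 0.0
        mid_y = layout.walkway_length / 2.0

    # Walk the polyline at dt steps; speed dips near the obstacle in
    # proportion to the margin deficit (full dip within 150 cm of the
    # obstacle midline, linear ramp outside).
    dt = 1.0 / params.trajectory_rate
    pts = [np.asarray(w, dtype=float) for w in waypoints]
    seg_lengths = [float(np.linalg.norm(b - a)) for a, b in zip(pts, pts[1:])]
    total_len = sum(seg_lengths)
    samples = [(0.0, 0.0, 0.0)]
    s = 0.0
    t = 0.0
    while s < total_len:
        pos = _point_at(pts, seg_lengths, s)
        dip = max(0.0, 1.0 - abs(pos[1] - mid_y) / 150.0)
        speed = max(params.speed_base - params.speed_margin_slowdown * deficit * dip, 20.0)
        s = min(s + speed * dt, total_len)
        t += dt
        x, y = _point_at(pts, seg_lengths, s)
        samples.append((t, x, y))

    arr = np.asarray(samples)
    jitter = rng.normal(0.0, params.trajectory_jitter_sd, size=(len(arr), 2))
    jitter[0] = 0.0  # trials start exactly at the origin
    frames = []
    for stream, lateral in (("body", 0.0), ("ankle_left", -9.0), ("ankle_right", 9.0)):
        frames.append(
            pd.DataFrame(
                {
                    "t_s": arr[:, 0],
                    "x_cm": arr[:, 1] + jitter[:, 0] + lateral,
                    "y_cm": arr[:, 2] + jitter[:, 1],
                    "stream": stream,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _point_at(pts: list, seg_lengths: list, s: float) -> tuple[float, float]:
    for a, b, length in zip(pts, pts[1:], seg_lengths):
        if s <= length or b is pts[-1]:
            frac = 0.0 if length == 0 else min(s / length, 1.0)
            p = a + frac * (b - a)
            return float(p[0]), float(p[1])
        s -= length
    p = pts[-1]
    return float(p[0]), float(p[1])


def _condition_phases(
    params: SimParams, layout: WalkwayLayout
) -> tuple[GazePhase, ...]:
    """Condition-specific phase model: narrower margins pull gaze from the
    target to the margin AOIs; the no-obstacle layout gets no margin gaze."""
    if not layout.has_obstacle:
        out = []
        for phase in params.gaze_phases:
            p = dict(phase.probs)
            p["T"] = p.get("T", 0.0) + 0.8 * p.pop("S", 0.0)
            p["none"] = p.get("none", 0.0) + 0.2 / 0.8 * (p["T"] - phase.probs["T"]) * 0.8
            total = sum(p.values())
            out.append(GazePhase(phase.end, {k: v / total for k, v in p.items()}))
        return tuple(out)
    am_left, am_right = lay.avoidance_margins(layout)
    deficit = max(0.0, params.margin_attention_ref - min(am_left, am_right))
    boost = 1.0 + deficit / params.margin_attention_ref
    out = []
    for phase in params.gaze_phases:
        p = dict(phase.probs)
        p["S"] = p["S"] * boost
        total = sum(p.values())
        out.append(GazePhase(phase.end, {k: v / total for k, v in p.items()}))
    return tuple(out)


def simulate_gaze(
    layout: WalkwayLayout,
    chosen_side: str | None,
    duration_s: float,
    params: SimParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phase-dependent categorical AOI stream with ground-plane coordinates.

    Margin gaze lands on the to-be-chosen side with probability
    ``margin_gaze_choice_bias`` so AMGR correlates with choice.
    """
    regions = AoiRegions.from_layout(layout)
    n = max(int(round(duration_s * params.gaze_rate)), 2)
    t = np.arange(n) / params.gaze_rate
    phases = _condition_phases(params, layout)
    half = layout.walkway_width / 2.0

    tokens = ("T", "P", "S", "none")
    # per-sample categorical probabilities from the active phase
    probs = np.zeros((n, len(tokens)))
    frac = t / duration_s
    lo = 0.0
    for phase in phases:
        mask = (frac > lo - 1e-12) & (frac <= phase.end + 1e-12)
        for k, tok in enumerate(tokens):
            probs[mask, k] = phase.probs.get(tok, 0.0)
        lo = phase.end
    probs[frac > lo] = probs[-1]
    u = rng.random(n)
    draw = (u[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)

    x = np.empty(n)
    y = np.empty(n)
    for k, tok in enumerate(tokens):
        idx = np.flatnonzero(draw == k)
        if idx.size == 0:
            continue
        if tok == "S" and regions.has_margins:
            on_chosen = rng.random(idx.size) < params.margin_gaze_choice_bias
            side_right = on_chosen == (chosen_side == RIGHT)
            for rect, sel in (
                (regions.am_right, idx[side_right]),
                (regions.am_left, idx[~side_right]),
            ):
                x[sel] = rng.uniform(rect.xmin, rect.xmax, sel.size)
                y[sel] = rng.uniform(rect.ymin, rect.ymax, sel.size)
        elif tok == "T" or (tok == "S" and not regions.has_margins):
            rect = regions.target
            x[idx] = rng.uniform(rect.xmin, rect.xmax, idx.size)
            y[idx] = rng.uniform(rect.ymin, rect.ymax, idx.size)
        elif tok == "P":
            # path strip between start and the margin band / target zone
            y_hi = (
                layout.obstacle_distance - 25.0
                if layout.has_obstacle
                else layout.walkway_length - 15.0
            )
            x[idx] = rng.uniform(-half * 0.8, half * 0.8, idx.size)
            y[idx] = rng.uniform(5.0, max(y_hi, 10.0), idx.size)
        else:  # off-AOI: beyond the walkway edge
            sign = np.where(rng.random(idx.size) < 0.5, 1.0, -1.0)
            x[idx] = rng.uniform(half + 5.0, half + 60.0, idx.size) * sign
            y[idx] = rng.uniform(0.0, layout.walkway_length, idx.size)
    return pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": y})


def simulate_judgment(
    offsets: Sequence[float],
    params: SimParams,
    rng: np.random.Generator,
    n_raters: int | None = None,
) -> pd.DataFrame:
    """0-10 side ratings over target offsets from a logistic psychometric.

    ``rating = clip(10 * P(right) + noise, 0, 10)`` with
    ``P(right) = expit(slope * (offset - threshold))``.
    """
    offsets = [float(o) for o in offsets]
    if any(abs(o) > 35.0 + 1e-9 for o in offsets):
        raise ValueError("judgment offsets must lie within +-35 cm")
    n_raters = n_raters or params.n_participants
    rows = []
    for rater in range(n_raters):
        for off in offsets:
            p = expit(params.judgment_slope * (off - params.judgment_threshold))
            rating = float(
                np.clip(10.0 * p + rng.normal(0.0, params.judgment_noise_sd), 0.0, 10.0)
            )
            rows.append({"rater": rater, "offset_cm": off, "rating": rating})
    return pd.DataFrame(rows)


def generate_dataset(params: SimParams) -> tuple[list[Trial], dict]:
    """Full design (8 conditions x 3 targets x n trials) per participant.

    Returns the trial list and a truth record of the generating parameters
    (for recovery tests).  Byte-identical across runs with the same params.
    """
    root = np.random.SeedSequence(params.seed)
    participant_seeds = root.spawn(params.n_participants)
    trials: list[Trial] = []
    design = lay.full_design()
    layouts = {cid: lay.build_layout(cid) for cid in range(1, 9)}
    for pid, pseed in enumerate(participant_seeds):
        prng = np.random.Generator(np.random.PCG64(pseed))
        jitter = prng.uniform(
            1.0 - params.participant_jitter, 1.0 + params.participant_jitter, size=5
        )
        coef = params.choice.scaled(jitter)
        for cid, offset in design:
            layout = layouts[cid]
            features = lay.geometry_features(layout, TargetPosition(offset))
            for rep in range(params.n_trials_per_cell):
                rng = np.random.Generator(np.random.PCG64(pseed.spawn(1)[0]))
                if layout.has_obstacle:
                    side = simulate_choice(features, coef, rng)
                else:
                    side = RIGHT if offset > 0 else LEFT if offset < 0 else RIGHT
                trajectory = simulate_trajectory(
                    layout, side if layout.has_obstacle else None, params, rng,
                    TargetPosition(offset),
                )
                duration = float(trajectory["t_s"].max())
                gaze = simulate_gaze(layout, side, duration, params, rng)
                p_foot = params.start_foot_p_right.get(offset, 0.6)
                p_foot += params.start_foot_side_pull * (1 if side == RIGHT else -1)
                foot = RIGHT if rng.random() < np.clip(p_foot, 0.0, 1.0) else LEFT
                trials.append(
                    Trial(
                        trial_id=f"p{pid:02d}_c{cid}_t{offset:+.0f}_r{rep}",
                        participant_id=pid,
                        condition_id=cid,
                        target_offset_cm=offset,
                        chosen_side=side,
                        start_foot=foot,
                        duration_s=duration,
                        trajectory=trajectory,
                        gaze=gaze,
                    )
                )
    truth = {"params": params.to_dict(), "n_trials": len(trials)}
    return trials, truth


def trials_to_frames(trials: Sequence[Trial]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(metadata frame, long samples frame) ready for CSV export."""
    meta = pd.DataFrame(
        [
            {
                "trial_id": tr.trial_id,
                "participant_id": tr.participant_id,
                "condition": tr.condition_id,
                "target_offset_cm": tr.target_offset_cm,
                "chosen_side": tr.chosen_side,
                "start_foot": tr.start_foot,
                "duration_s": tr.duration_s,
            }
            for tr in trials
        ]
    )
    sample_frames = []
    for tr in trials:
        traj = tr.trajectory.copy()
        traj["trial_id"] = tr.trial_id
        gz = tr.gaze.copy()
        gz["stream"] = "gaze"
        gz["trial_id"] = tr.trial_id
        sample_frames.append(traj)
        sample_frames.append(gz)
    samples = pd.concat(sample_frames, ignore_index=True)[
        ["trial_id", "stream", "t_s", "x_cm", "y_cm"]
    ]
    return meta, samples


def trials_from_frames(meta: pd.DataFrame, samples: pd.DataFrame) -> list[Trial]:
    """Inverse of :func:`trials_to_frames`."""
    grouped = dict(tuple(samples.groupby("trial_id", sort=False)))
    trials = []
    for row in meta.itertuples(index=False):
        chunk = grouped[row.trial_id]
        trajectory = (
            chunk[chunk["stream"] != "gaze"][["t_s", "x_cm", "y_cm", "stream"]]
            .reset_index(drop=True)
        )
        gaze = (
            chunk[chunk["stream"] == "gaze"][["t_s", "x_cm", "y_cm"]]
            .reset_index(drop=True)
        )
        trials.append(
            Trial(
                trial_id=row.trial_id,
                participant_id=int(row.participant_id),
                condition_id=int(row.condition),
                target_offset_cm=float(row.target_offset_cm),
                chosen_side=row.chosen_side,
                start_foot=row.start_foot,
                duration_s=float(row.duration_s),
                trajectory=trajectory,
                gaze=gaze,
            )
        )
    return trials


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
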