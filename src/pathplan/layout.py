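"""Walkway/obstacle geometry and the decision-feature families.

The coordinate frame has its origin at the center of the starting position,
x pointing laterally (+ = walker's right) and y pointing forward toward the
bookcase.  All lengths are centimeters, all angles degrees.

Three feature families are derived from a layout:

* relative distance  -- ``D_L``, ``D_R`` (start to the obstacle front-face
  outer corners) and their difference ``delta_d = D_R - D_L``;
* deviation angles   -- ``theta_L``, ``theta_R`` (unsigned angle between the
  start->target ray and the start->corner ray) and
  ``delta_theta = theta_R - theta_L``;
* avoidance margins  -- ``am_left``, ``am_right`` (obstacle outer edge to
  walkway edge) and their ratio ``amr = am_right / am_left``.

Sign conventions: an obstacle shifted right gives ``delta_d > 0``; a target
shifted left gives ``delta_theta > 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "LayoutError",
    "WalkwayLayout",
    "TargetPosition",
    "GeometryFeatures",
    "condition_table",
    "build_layout",
    "avoidance_margins",
    "derived_margins",
    "relative_distance",
    "deviation_angles",
    "straight_deviation_angle",
    "geometry_features",
    "feature_table",
    "full_design",
    "EXPERIMENT_TARGET_OFFSETS",
    "BOOKCASE_DEPTH",
]

#: Target lateral offsets used in the walking experiment (cm; + = right).
EXPERIMENT_TARGET_OFFSETS = (-30.0, 0.0, 30.0)

#: Bookcase depth (cm); used by gaze AOI construction downstream.
BOOKCASE_DEPTH = 22.0


class LayoutError(ValueError):
    """Invalid walkway geometry or an operation on an incompatible layout."""


@dataclass(frozen=True)
class WalkwayLayout:
    """Physical geometry of the walkway, obstacle, and bookcase for one condition."""

    walkway_width: float = 213.0
    walkway_length: float = 750.0
    tape_width: float = 5.0
    obstacle_width: float = 0.0  # 0 -> no obstacle
    obstacle_depth: float = 32.0
    obstacle_lateral_offset: float = 0.0  # + = shifted right of centerline
    obstacle_distance: float = 375.0  # start line to obstacle front face
    shelf_height: float = 88.0
    bookcase_width: float = 90.0
    am_left_override: float | None = None
    am_right_override: float | None = None
    condition_id: int | None = None

    def __post_init__(self) -> None:
        if self.walkway_width <= 0 or self.walkway_length <= 0:
            raise LayoutError("walkway dimensions must be positive")
        if self.obstacle_width < 0:
            raise LayoutError("obstacle_width must be >= 0")
        if self.has_obstacle:
            if self.obstacle_width + 2 * abs(self.obstacle_lateral_offset) > self.walkway_width:
                raise LayoutError(
                    f"obstacle (width {self.obstacle_width}, offset "
                    f"{self.obstacle_lateral_offset}) does not fit on a "
                    f"{self.walkway_width} cm walkway"
                )
            if not 0 < self.obstacle_distance < self.walkway_length:
                raise LayoutError("obstacle_distance must lie within the walkway")
        for name in ("am_left_override", "am_right_override"):
            value = getattr(self, name)
            if value is not None and not 0 < value <= self.walkway_width:
                raise LayoutError(f"{name}={value} outside (0, walkway_width]")

    @property
    def has_obstacle(self) -> bool:
        return self.obstacle_width > 0

    @property
    def obstacle_edges(self) -> tuple[float, float]:
        """Lateral x of the obstacle's (left, right) outer edges."""
        self._require_obstacle()
        half = self.obstacle_width / 2.0
        return (self.obstacle_lateral_offset - half, self.obstacle_lateral_offset + half)

    def front_corners(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(x, y) of the front-face outer corners, left then right."""
        left, right = self.obstacle_edges
        return (left, self.obstacle_distance), (right, self.obstacle_distance)

    def _require_obstacle(self) -> None:
        if not self.has_obstacle:
            raise LayoutError("operation undefined for the no-obstacle layout")


@dataclass(frozen=True)
class TargetPosition:
    """Lateral target offset on the lower shelf (cm; + = right of shelf center)."""

    lateral_offset: float = 0.0

    def validate(self, layout: WalkwayLayout) -> "TargetPosition":
        if abs(self.lateral_offset) > layout.bookcase_width / 2.0:
            raise LayoutError(
                f"target offset {self.lateral_offset} beyond the "
                f"{layout.bookcase_width} cm bookcase"
            )
        return self

    def point(self, layout: WalkwayLayout) -> tuple[float, float]:
        return (self.lateral_offset, layout.walkway_length)


@dataclass(frozen=True)
class GeometryFeatures:
    """Decision variables for one condition x target cell.

    Obstacle-dependent fields are ``None`` for the no-obstacle baseline,
    where only the deviation angle from straight ahead is defined.
    """

    condition_id: int | None
    target_offset_cm: float
    d_left: float | None
    d_right: float | None
    delta_d: float | None
    theta_left: float | None
    theta_right: float | None
    delta_theta: float | None
    am_left: float | None
    am_right: float | None
    amr: float | None
    straight_angle: float  # angle from straight ahead to the target ray

    @property
    def has_obstacle(self) -> bool:
        return self.delta_d is not None


def _load_condition_specs() -> dict[int, dict]:
    text = resources.files("pathplan.data").joinpath("conditions.yaml").read_text()
    raw = yaml.safe_load(text)["conditions"]
    return {int(k): dict(v) for k, v in raw.items()}


_CONDITION_SPECS = _load_condition_specs()


def condition_table() -> pd.DataFrame:
    """Published condition registry as a data frame (one row per condition)."""
    rows = []
    for cid in sorted(_CONDITION_SPECS):
        layout = build_layout(cid)
        am_l, am_r = (
            avoidance_margins(layout) if layout.has_obstacle else (None, None)
        )
        rows.append(
            {
                "condition": cid,
                "obstacle_width": layout.obstacle_width or None,
                "obstacle_lateral_offset": (
                    layout.obstacle_lateral_offset if layout.has_obstacle else None
                ),
                "am_left": am_l,
                "am_right": am_r,
            }
        )
    return pd.DataFrame(rows)


def build_layout(spec: int | Mapping) -> WalkwayLayout:
    """Build a :class:`WalkwayLayout` from a condition id (1-8) or explicit geometry.

    Condition ids carry the published margin overrides; explicit geometry is
    validated against the layout invariants.
    """
    if isinstance(spec, Mapping):
        return WalkwayLayout(**spec)
    cid = int(spec)
    if cid not in _CONDITION_SPECS:
        raise LayoutError(f"unknown condition id {cid!r}; expected 1..8")
    return WalkwayLayout(condition_id=cid, **_CONDITION_SPECS[cid])


def derived_margins(layout: WalkwayLayout) -> tuple[float, float]:
    """Margins derived purely from geometry (ignores overrides)."""
    layout._require_obstacle()
    base = layout.walkway_width / 2.0 - layout.obstacle_width / 2.0
    am_left = base + layout.obstacle_lateral_offset
    am_right = base - layout.obstacle_lateral_offset
    if am_left <= 0 or am_right <= 0:
        raise LayoutError("derived avoidance margin is not positive")
    return am_left, am_right


def avoidance_margins(layout: WalkwayLayout) -> tuple[float, float]:
    """(am_left, am_right) in cm; overrides take precedence over derivation.

    The published margin table and symmetric derivation disagree by up to
    ~1 cm for some conditions; the overrides are treated as canonical.
    """
    layout._require_obstacle()
    if layout.am_left_override is not None and layout.am_right_override is not None:
        return layout.am_left_override, layout.am_right_override
    return derived_margins(layout)


def relative_distance(layout: WalkwayLayout) -> tuple[float, float, float]:
    """(d_left, d_right, delta_d): start-center to front-face outer corners."""
    (lx, ly), (rx, ry) = layout.front_corners()
    d_left = math.hypot(lx, ly)
    d_right = math.hypot(rx, ry)
    return d_left, d_right, d_right - d_left


def _angle_between_deg(ux: float, uy: float, vx: float, vy: float) -> float:
    return math.degrees(abs(math.atan2(ux * vy - uy * vx, ux * vx + uy * vy)))


def deviation_angles(
    layout: WalkwayLayout, target: TargetPosition
) -> tuple[float, float, float]:
    """(theta_left, theta_right, delta_theta) in degrees.

    Each theta is the unsigned angle between the start->target ray and the
    start->corner ray for that side's front-face outer corner.
    """
    target = target.validate(layout)
    tx, ty = target.point(layout)
    (lx, ly), (rx, ry) = layout.front_corners()
    theta_left = _angle_between_deg(tx, ty, lx, ly)
    theta_right = _angle_between_deg(tx, ty, rx, ry)
    return theta_left, theta_right, theta_right - theta_left


def straight_deviation_angle(layout: WalkwayLayout, target: TargetPosition) -> float:
    """Unsigned angle between straight ahead (the y axis) and the target ray."""
    tx, ty = target.validate(layout).point(layout)
    return _angle_between_deg(0.0, 1.0, tx, ty)


def geometry_features(
    layout: WalkwayLayout, target: TargetPosition
) -> GeometryFeatures:
    target = target.validate(layout)
    straight = straight_deviation_angle(layout, target)
    if not layout.has_obstacle:
        return GeometryFeatures(
            condition_id=layout.condition_id,
            target_offset_cm=target.lateral_offset,
            d_left=None,
            d_right=None,
            delta_d=None,
            theta_left=None,
            theta_right=None,
            delta_theta=None,
            am_left=None,
            am_right=None,
            amr=None,
            straight_angle=straight,
        )
    d_left, d_right, delta_d = relative_distance(layout)
    theta_left, theta_right, delta_theta = deviation_angles(layout, target)
    am_left, am_right = avoidance_margins(layout)
    return GeometryFeatures(
        condition_id=layout.condition_id,
        target_offset_cm=target.lateral_offset,
        d_left=d_left,
        d_right=d_right,
        delta_d=delta_d,
        theta_left=theta_left,
        theta_right=theta_right,
        delta_theta=delta_theta,
        am_left=am_left,
        am_right=am_right,
        amr=am_right / am_left,
        straight_angle=straight,
    )


def full_design(
    conditions: Sequence[int] = tuple(range(1, 9)),
    target_offsets: Sequence[float] = EXPERIMENT_TARGET_OFFSETS,
) -> list[tuple[int, float]]:
    """The condition x target cells of the experiment (24 by default)."""
    return [(c, t) for c in conditions for t in target_offsets]


def feature_table(design: Iterable[tuple[int | Mapping, float]]) -> pd.DataFrame:
    """One feature row per (condition spec, target offset) cell, order preserved."""
    cells = list(design)
    if not cells:
        raise LayoutError("empty design")
    rows = []
    for spec, offset in cells:
        feats = geometry_features(build_layout(spec), TargetPosition(offset))
        rows.append(
            {
                "condition": feats.condition_id,
                "target_offset_cm": feats.target_offset_cm,
                "d_left": feats.d_left,
                "d_right": feats.d_right,
                "delta_d": feats.delta_d,
                "theta_left": feats.theta_left,
                "theta_right": feats.theta_right,
                "delta_theta": feats.delta_theta,
                "am_left": feats.am_left,
                "am_right": feats.am_right,
                "amr": feats.amr,
                "straight_angle": feats.straight_angle,
            }
        )
    return pd.DataFrame(rows)


def mirrored(layout: WalkwayLayout) -> WalkwayLayout:
    """Left/right mirror of a layout (offset negated, overrides swapped)."""
    return replace(
        layout,
        obstacle_lateral_offset=-layout.obstacle_lateral_offset,
        am_left_override=layout.am_right_override,
        am_right_override=layout.am_left_override,
    )
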