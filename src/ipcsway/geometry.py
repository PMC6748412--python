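"""Intermittent-activation geometry on the (position, s*velocity) phase plane.

Active feedback is on when the lagged phase point lies outside the
insensitivity radius ``r`` AND on the active side of the switching line
``xdot = alpha * x`` (slope from :func:`ipcsway.model.alpha_from_a`).  When
two consecutive lagged states straddle the activation boundary, the filter
needs the crossing point and the split of the sampling interval; the
functions here classify the traversal (line / circle / axis), interpolate
the crossing, and split the interval in proportion to Euclidean distance.

All coordinates are in radians: velocities entering the geometry are
pre-multiplied by the seconds constant s = 1 s.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "PhasePoint",
    "TransitionKind",
    "CrossingCase",
    "TransitionEvent",
    "is_active",
    "classify_transition",
    "crossing_point",
    "split_interval",
    "detect_transition",
]


class PhasePoint(NamedTuple):
    """A lagged state on the phase plane; both components in radians."""

    pos: float
    vel_scaled: float


class TransitionKind(enum.Enum):
    NONE = "none"
    ON = "on"    #: inactive -> active across the interval
    OFF = "off"  #: active -> inactive across the interval


class CrossingCase(enum.Enum):
    LINE = "line"      #: traversing the switching line outside the radius
    CIRCLE = "circle"  #: traversing the insensitivity circle
    AXIS = "axis"      #: traversing the position axis x = 0


@dataclass(frozen=True)
class TransitionEvent:
    kind: TransitionKind
    case: CrossingCase | None
    crossing: PhasePoint | None
    dt_minus: float
    dt_plus: float


def is_active(pt: PhasePoint, alpha: float, r: float) -> bool:
    """Activation condition: ``pos*(vel - alpha*pos) > 0`` and
    ``pos^2 + vel^2 > r^2`` (both strict)."""
    p, v = pt
    if p * p + v * v <= r * r:
        return False
    return p * (v - alpha * p) > 0.0


def _case(u: PhasePoint, v: PhasePoint, r: float) -> CrossingCase:
    """Sub-case of an OFF traversal (for ON, call with roles traded).

    CIRCLE when the destination-side point is inside the radius; AXIS when
    the quadrant pattern shows the segment crossing x = 0 while staying on
    one side of the line; LINE otherwise.
    """
    if v.pos ** 2 + v.vel_scaled ** 2 <= r * r:
        return CrossingCase.CIRCLE
    axis = ((v.pos > 0 and v.vel_scaled < 0 and u.pos < 0 and u.vel_scaled < 0)
            or
            (v.pos < 0 and v.vel_scaled > 0 and u.pos > 0 and u.vel_scaled > 0))
    return CrossingCase.AXIS if axis else CrossingCase.LINE


def classify_transition(u: PhasePoint, v: PhasePoint, alpha: float,
                        r: float) -> tuple[TransitionKind, CrossingCase | None]:
    """Classify the activation change between consecutive lagged states."""
    au = is_active(u, alpha, r)
    av = is_active(v, alpha, r)
    if au == av:
        return TransitionKind.NONE, None
    if au:  # active -> inactive
        return TransitionKind.OFF, _case(u, v, r)
    return TransitionKind.ON, _case(v, u, r)


def _midpoint(u: PhasePoint, v: PhasePoint) -> PhasePoint:
    return PhasePoint(0.5 * (u.pos + v.pos),
                      0.5 * (u.vel_scaled + v.vel_scaled))


def crossing_point(u: PhasePoint, v: PhasePoint, alpha: float, r: float,
                   case: CrossingCase,
                   switching_on: bool = False) -> PhasePoint:
    """Interpolated point where the segment u -> v meets the boundary.

    LINE: intersection with ``xdot = alpha x`` (exact, lies on the line).
    CIRCLE: first-order interpolation onto the insensitivity circle around
    the destination-side point (not exactly on the circle).  AXIS:
    intersection with ``x = 0``.  For switching ON the roles of u and v
    are traded before applying the same formulas.  All cases return a
    point on the infinite line through u and v; degenerate segments
    (zero length, or parallel to the switching line) fall back to the
    shared point / midpoint.
    """
    if switching_on:
        u, v = v, u
    du = v.pos - u.pos
    dv = v.vel_scaled - u.vel_scaled
    if du * du + dv * dv < 1e-300:
        return u
    if abs(du) < 1e-14 * (abs(dv) + 1.0):
        # vertical segment: slope undefined
        warnings.warn("degenerate (vertical) phase segment; using midpoint")
        return _midpoint(u, v)
    m = dv / du
    if case is CrossingCase.CIRCLE:
        den = 2.0 * (v.pos + m * v.vel_scaled)
        if abs(den) < 1e-14:
            warnings.warn("degenerate circle crossing; using midpoint")
            return _midpoint(u, v)
        cp = (r * r + v.pos ** 2 + 2.0 * m * v.pos * v.vel_scaled
              - v.vel_scaled ** 2) / den
        return PhasePoint(cp, m * cp - m * v.pos + v.vel_scaled)
    if case is CrossingCase.AXIS:
        return PhasePoint(0.0, v.vel_scaled - m * v.pos)
    # LINE
    if abs(alpha - m) < 1e-14 * (abs(alpha) + abs(m) + 1.0):
        warnings.warn("phase segment parallel to switching line; "
                      "using midpoint")
        return _midpoint(u, v)
    cp = (v.vel_scaled - m * v.pos) / (alpha - m)
    return PhasePoint(cp, m * cp - m * v.pos + v.vel_scaled)


def split_interval(u: PhasePoint, v: PhasePoint, crossing: PhasePoint,
                   dt: float) -> tuple[float, float]:
    """Split ``dt`` proportionally to distance along the segment u -> v.

    The crossing is projected onto the segment and clamped to it, so
    ``dt_minus + dt_plus == dt`` exactly and both parts are non-negative.
    """
    du = v.pos - u.pos
    dv = v.vel_scaled - u.vel_scaled
    seg2 = du * du + dv * dv
    if seg2 < 1e-300:
        return 0.0, dt
    t = ((crossing.pos - u.pos) * du
         + (crossing.vel_scaled - u.vel_scaled) * dv) / seg2
    t = min(max(t, 0.0), 1.0)
    return t * dt, (1.0 - t) * dt


def detect_transition(u: PhasePoint, v: PhasePoint, alpha: float, r: float,
                      dt: float) -> TransitionEvent:
    """Full traversal description for one sampling interval."""
    kind, case = classify_transition(u, v, alpha, r)
    if kind is TransitionKind.NONE:
        return TransitionEvent(kind, None, None, dt, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        crossing = crossing_point(u, v, alpha, r, case,
                                  switching_on=(kind is TransitionKind.ON))
    dtm, dtp = split_interval(u, v, crossing, dt)
    # keep the reported crossing consistent with the clamped split
    if dtm == 0.0:
        crossing = u
    elif dtp == 0.0:
        crossing = v
    return TransitionEvent(kind, case, crossing, dtm, dtp)
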