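"""Forager embodiment: bilateral sensors, perceptual gating, motor dynamics,
and toroidal kinematics.

The body is a point agent in a wrap-around square arena.  Two distance
sensors sit at ``±o/2`` perpendicular to the heading; each reads
``gain * (1 - dist/d)`` of the toroidal Euclidean distance to the target,
clamped at 0 beyond the detection radius ``d``.  Motor neurons drive
velocity and turn rate:

    dv/dt = -v*f + (o1 + o2) * delta        (drag form; see note below)
    dq/dt = (o1 - o2) * eps - q

so the top speed is ``2*delta/f``.  The alternative drag form
``dv/dt = -v*(1-f) + ...`` is available via ``printed_drag_form`` but gives
an implausible top speed of ``2*delta/(1-f)`` with the default drag 0.9.

Movement-dependent (D) foragers receive no sensor input whenever their
velocity exceeds the perceptual threshold ``phi``: they must slow to a near
stop to "sample" for signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BodyParams",
    "BodyState",
    "toroidal_delta",
    "toroidal_distance",
    "wrap_angle",
    "sensor_positions",
    "sensor_values",
    "gate_perception",
    "step_motor",
    "step_kinematics",
]

DEFAULT_ARENA_SIDE = 100.0


@dataclass
class BodyParams:
    """Perceptual and movement parameters of the forager.

    Defaults are the task's standard values: drag f=0.9, max exertion
    delta=2, max turn eps=pi/6, sensor gain gamma=3, sensor offset o=2
    (equal to the interaction radius, i.e. the body radius), detection
    radius d=29, interaction radius lambda=2, perceptual threshold phi=0.01.
    """

    drag: float = 0.9
    max_exertion: float = 2.0
    max_turn: float = math.pi / 6
    sensor_gain: float = 3.0
    sensor_offset: float = 2.0
    detection_radius: float = 29.0
    interaction_radius: float = 2.0
    perception_threshold: float = 0.01
    movement_dependent: bool = False
    printed_drag_form: bool = False
    arena_side: float = DEFAULT_ARENA_SIDE

    def __post_init__(self) -> None:
        if not 0 < self.drag < 1:
            raise ValueError("drag must lie in (0, 1)")
        if self.detection_radius <= self.interaction_radius:
            raise ValueError("detection radius must exceed interaction radius")
        if self.sensor_offset > 2 * self.interaction_radius:
            raise ValueError("sensor offset cannot exceed the body diameter")
        if self.arena_side <= self.detection_radius:
            raise ValueError("arena side must exceed the detection radius")

    @property
    def max_speed(self) -> float:
        f = (1 - self.drag) if self.printed_drag_form else self.drag
        return 2 * self.max_exertion / f


@dataclass
class BodyState:
    """Kinematic state: position (arena units), heading alpha in (-pi, pi],
    velocity v >= 0, and turn rate q (rad / time unit)."""

    position: np.ndarray
    heading: float = 0.0
    velocity: float = 0.0
    turn_rate: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)

    def copy(self) -> "BodyState":
        return BodyState(self.position.copy(), self.heading,
                         self.velocity, self.turn_rate)


def wrap_angle(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    if a > math.pi:
        a -= 2 * math.pi
    elif a <= -math.pi:
        a += 2 * math.pi
    if a > math.pi or a <= -math.pi:  # input far outside one period
        a = (a + math.pi) % (2 * math.pi) - math.pi
        if a == -math.pi:
            a = math.pi
    return a


def wrap_coord(a: float, side: float) -> float:
    """Fold a coordinate within one arena period back into [0, side)."""
    if a >= side:
        return a - side
    if a < 0.0:
        return a + side
    return a


def toroidal_delta(p, q, side: float):
    """Signed minimal-image displacement q - p on the torus."""
    d = (np.asarray(q, dtype=float) - np.asarray(p, dtype=float)) % side
    return np.where(d > side / 2, d - side, d)


def toroidal_distance(p, q, side: float) -> float:
    """Minimal-image Euclidean distance between two points on the torus
    (both already folded into [0, side))."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    dx = abs(p[0] - q[0])
    if dx > side / 2:
        dx = side - dx
    dy = abs(p[1] - q[1])
    if dy > side / 2:
        dy = side - dy
    return math.sqrt(dx * dx + dy * dy)


def sensor_positions(body: BodyState, params: BodyParams):
    """Left and right sensor coordinates: body center displaced by
    ``sensor_offset/2`` perpendicular to the heading (left = +90 degrees
    counterclockwise), wrapped into the arena."""
    half = params.sensor_offset / 2
    side = params.arena_side
    sh = math.sin(body.heading)
    ch = math.cos(body.heading)
    px, py = body.position
    left = np.array([wrap_coord(px - half * sh, side),
                     wrap_coord(py + half * ch, side)])
    right = np.array([wrap_coord(px + half * sh, side),
                      wrap_coord(py - half * ch, side)])
    return left, right


def sensor_values(body: BodyState, target, params: BodyParams):
    """Raw bilateral sensor readings ``(s_left, s_right)``.

    Each is ``gain * (1 - dist(sensor, target) / d)`` with toroidal
    Euclidean distance, clamped below at 0 (no anti-signal beyond the
    detection radius).  A target dead ahead reads identically on both sides.
    """
    left, right = sensor_positions(body, params)
    side = params.arena_side
    s_l = params.sensor_gain * (1 - toroidal_distance(left, target, side)
                                / params.detection_radius)
    s_r = params.sensor_gain * (1 - toroidal_distance(right, target, side)
                                / params.detection_radius)
    return max(0.0, s_l), max(0.0, s_r)


def gate_perception(raw, signal_on: bool, body: BodyState,
                    params: BodyParams):
    """Apply signal availability and movement-dependence to raw sensor values.

    Returns ``(0, 0)`` when the target is not signaling, or when a
    movement-dependent forager is moving faster than the perceptual
    threshold phi; otherwise passes the raw values through unchanged.
    """
    if not signal_on:
        return 0.0, 0.0
    if params.movement_dependent and body.velocity > params.perception_threshold:
        return 0.0, 0.0
    return float(raw[0]), float(raw[1])


def step_motor(body: BodyState, o1: float, o2: float, params: BodyParams,
               dt: float) -> BodyState:
    """Euler-update velocity and turn rate from the motor outputs o1, o2
    (each in [0, 1]).  Velocity is floored at 0 (belt-and-braces: the drag
    form cannot cross zero from a non-negative state at this step size)."""
    f = (1 - params.drag) if params.printed_drag_form else params.drag
    dv = -body.velocity * f + (o1 + o2) * params.max_exertion
    dq = (o1 - o2) * params.max_turn - body.turn_rate
    out = body.copy()
    out.velocity = max(0.0, body.velocity + dt * dv)
    out.turn_rate = body.turn_rate + dt * dq
    return out


def step_kinematics(body: BodyState, dt: float, arena_side: float):
    """Integrate heading and position for one step.

    Heading integrates the turn rate first (wrapped to (-pi, pi]), then the
    body advances ``v*dt`` along the new heading, wrapped into [0, L).
    Returns ``(new_state, displacement)`` where displacement is the per-step
    path-length increment ``v*dt``.
    """
    out = body.copy()
    out.heading = wrap_angle(body.heading + body.turn_rate * dt)
    step = body.velocity * dt
    out.position = np.array([
        wrap_coord(body.position[0] + step * math.cos(out.heading),
                   arena_side),
        wrap_coord(body.position[1] + step * math.sin(out.heading),
                   arena_side)])
    return out, step
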