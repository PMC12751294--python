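"""Pursuit-trial environment: target placement, signal schedules, the trial
loop, and the chemotaxis-index fitness function.

A trial starts with randomized neural states in [0, 1], a transient of
``T_T`` time units with zero input, then an "encounter": the target appears
at a distance r0 ~ U[23, 27] at a bearing relative to the forager's heading.
The trial runs up to ``T`` time units and ends early only when the forager
is within the interaction radius and effectively stopped (an "attack").

Fitness is piecewise in the final distance r_n:

    F = 0                                             r_n > d   (target lost)
    F = 1 - r_n/r0                                    d >= r_n >= lambda
    F = (1 - r_n/r0) + r0/z + (1 - t_n/T)             r_n <= lambda (attack)

with route-efficiency (r0/z, z = path length) and time-efficiency bonuses
on capture.  Foragers are evaluated as the mean F over a 24-bearing battery
spanning direct left (-pi/2) to direct right (+pi/2) at pi/24 spacing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .body import (BodyParams, BodyState, gate_perception, sensor_values,
                   step_kinematics, step_motor, toroidal_distance,
                   wrap_coord)
from .network import NetworkParams, neuron_output, step_network

__all__ = [
    "TaskConfig",
    "SignalSchedule",
    "TrialResult",
    "battery_bearings",
    "make_signal_schedule",
    "place_target",
    "trial_fitness",
    "run_trial",
    "evaluate_forager",
    "trajectory_to_csv",
    "TRAJECTORY_COLUMNS",
]

TRAJECTORY_COLUMNS = ("time", "x", "y", "heading", "velocity", "turn_rate",
                      "s1", "s2", "signal_on", "i1", "i2", "target_distance",
                      "x1", "x2", "x3", "x4", "x5")


@dataclass
class TaskConfig:
    """Trial parameters.  Defaults are the standard task values: duration
    T=600, transient T_T=100, dt=0.05, r0 in [23, 27], unreliable signal
    fraction s_P=0.3 over s_I=20 intervals."""

    duration: float = 600.0
    transient: float = 100.0
    dt: float = 0.05
    r0_min: float = 23.0
    r0_max: float = 27.0
    signal_reliable: bool = True
    signal_fraction: float = 0.3
    signal_intervals: int = 20
    n_bearings: int = 24

    def __post_init__(self) -> None:
        if not 0 < self.signal_fraction <= 1:
            raise ValueError("signal_fraction must lie in (0, 1]")
        if self.signal_intervals < 1:
            raise ValueError("signal_intervals must be >= 1")
        if self.dt <= 0 or self.duration <= 0 or self.transient < 0:
            raise ValueError("invalid timing parameters")
        if self.n_steps % self.signal_intervals != 0:
            raise ValueError("trial steps must divide evenly into intervals")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_transient_steps(self) -> int:
        return int(round(self.transient / self.dt))

    @property
    def steps_per_interval(self) -> int:
        return self.n_steps // self.signal_intervals

    @property
    def block_steps(self) -> int:
        """Steps per unreliable on-block: s_P * T / s_I time units."""
        return int(round(self.signal_fraction * self.steps_per_interval))


@dataclass
class SignalSchedule:
    """Per-integration-step boolean signal availability over one trial."""

    on: np.ndarray  # (n_steps,) uint8
    offsets: np.ndarray | None = None  # per-interval block offsets (steps)

    @property
    def on_fraction(self) -> float:
        return float(np.mean(self.on))

    def run_length_encode(self) -> list[tuple[int, int, int]]:
        """(value, start, length) runs, for human inspection/export."""
        on = np.asarray(self.on, dtype=np.uint8)
        edges = np.flatnonzero(np.diff(on)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [on.size]))
        return [(int(on[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


@dataclass
class TrialResult:
    """Outcome of one pursuit trial."""

    r_final: float
    r0: float
    path_length: float
    t_end: float  # elapsed time units
    attacked: bool
    fitness: float
    diverged: bool = False
    trajectory: np.ndarray | None = None


def battery_bearings(n: int = 24) -> np.ndarray:
    """The evaluation bearings: n values at pi/n spacing from direct left
    (-pi/2, inclusive) toward direct right (+pi/2, exclusive)."""
    return -math.pi / 2 + math.pi / n * np.arange(n)


def draw_schedule_offsets(config: TaskConfig, rng: np.random.Generator,
                          size=()) -> np.ndarray:
    """Uniform admissible per-interval block offsets (in steps)."""
    hi = config.steps_per_interval - config.block_steps
    return rng.integers(0, hi + 1,
                        size=tuple(size) + (config.signal_intervals,))


def offsets_to_schedule(offsets: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Materialize per-step uint8 availability from block offsets.
    Supports leading batch dimensions."""
    spi = config.steps_per_interval
    local = np.arange(spi)
    on = ((local >= offsets[..., None])
          & (local < offsets[..., None] + config.block_steps))
    return on.reshape(offsets.shape[:-1] + (-1,)).astype(np.uint8)


def make_signal_schedule(config: TaskConfig,
                         rng: np.random.Generator) -> SignalSchedule:
    """Draw one signal schedule.

    Reliable targets signal at every step.  Unreliable targets signal for a
    single contiguous block of ``s_P * T / s_I`` time units at a uniformly
    random admissible offset within each of the s_I equal intervals.
    """
    if config.signal_reliable:
        return SignalSchedule(on=np.ones(config.n_steps, dtype=np.uint8))
    if config.block_steps > config.steps_per_interval:
        raise ValueError("signal block longer than interval (s_P > 1)")
    offsets = draw_schedule_offsets(config, rng)
    return SignalSchedule(on=offsets_to_schedule(offsets, config),
                          offsets=offsets)


def place_target(body: BodyState, bearing: float, config: TaskConfig,
                 rng: np.random.Generator, arena_side: float) -> np.ndarray:
    """Place the target at a drawn distance r0 ~ U[r0_min, r0_max] along
    ``heading - bearing``.

    The bearing convention follows the task definition: direct left is
    -pi/2 and direct right is +pi/2, i.e. positive bearings are clockwise
    from the heading.  During evolution bearings lie in [-pi/2, pi/2]
    (targets never appear behind the forager); analysis code may pass any
    bearing.
    """
    r0 = rng.uniform(config.r0_min, config.r0_max)
    ang = body.heading - bearing
    return np.array([
        wrap_coord(body.position[0] + r0 * math.cos(ang), arena_side),
        wrap_coord(body.position[1] + r0 * math.sin(ang), arena_side)])


def trial_fitness(r_final: float, r0: float, path_length: float,
                  t_end: float, config: TaskConfig, body: BodyParams,
                  attacked: bool | None = None) -> float:
    """Piecewise chemotaxis-index fitness (see module docstring).

    The middle branch is not clamped below: a forager that ends farther
    from the target than it started (but still inside d) scores negative.
    A tie at exactly ``r_final == lambda`` takes the attack branch unless
    the caller explicitly marks the trial as not attacked.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if path_length < 0:
        raise ValueError("path_length must be non-negative")
    d = body.detection_radius
    lam = body.interaction_radius
    if r_final > d:
        return 0.0
    middle = 1.0 - r_final / r0
    attack_branch = r_final < lam or (r_final == lam and attacked is not False)
    if not attack_branch:
        return middle
    if path_length == 0.0:
        warnings.warn("attack branch with zero path length; "
                      "returning middle-branch value", stacklevel=2)
        return middle
    return middle + r0 / path_length + (1.0 - t_end / config.duration)


def _phenotype_tuple(params: NetworkParams):
    return (np.ascontiguousarray(params.tau),
            np.ascontiguousarray(params.theta),
            np.ascontiguousarray(params.w_syn),
            np.ascontiguousarray(params.w_sens))


def run_trial(params: NetworkParams, bearing: float, task: TaskConfig,
              body: BodyParams, rng: np.random.Generator, *,
              r0: float | None = None, x0: np.ndarray | None = None,
              schedule: SignalSchedule | np.ndarray | None = None,
              record: bool = False, terminate_on_attack: bool = True,
              engine: str = "fast") -> TrialResult:
    """Run one full pursuit trial and score it.

    Randomized quantities (initial neural state in [0, 1], r0, unreliable
    schedule) are drawn from ``rng`` unless passed explicitly.  With
    ``record=True`` the result carries a per-step trajectory array with
    columns ``TRAJECTORY_COLUMNS``.  ``engine="reference"`` runs the slow
    pure-Python loop built from the public ops (used for cross-checking the
    compiled kernel).
    """
    n = params.n_neurons
    if x0 is None:
        x0 = rng.uniform(0.0, 1.0, n)
    x0 = np.asarray(x0, dtype=float)
    if r0 is None:
        r0 = float(rng.uniform(task.r0_min, task.r0_max))
    if schedule is None:
        schedule = make_signal_schedule(task, rng)
    on = schedule.on if isinstance(schedule, SignalSchedule) else \
        np.asarray(schedule, dtype=np.uint8)
    if on.shape[0] != task.n_steps:
        raise ValueError("schedule length must equal the trial step count")

    drag_eff = (1 - body.drag) if body.printed_drag_form else body.drag
    if engine == "fast":
        traj = np.empty((task.n_steps, _kernels.TRAJ_BASE_COLS + n)) \
            if record else np.empty((1, 1))
        r_final, z, t_end_steps, status = _kernels.simulate_trial(
            *_phenotype_tuple(params), x0, on, float(bearing), float(r0),
            body.arena_side, task.dt, task.n_transient_steps, task.n_steps,
            drag_eff, body.max_exertion, body.max_turn,
            body.sensor_gain, body.sensor_offset, body.detection_radius,
            body.interaction_radius, body.perception_threshold,
            body.movement_dependent, terminate_on_attack, record, traj)
        t_end_steps = int(t_end_steps)
        trajectory = traj[:t_end_steps] if record else None
    elif engine == "reference":
        r_final, z, t_end_steps, status, trajectory = _reference_trial(
            params, x0, on, bearing, r0, task, body, terminate_on_attack,
            record)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    attacked = status == _kernels.STATUS_ATTACKED
    diverged = status == _kernels.STATUS_NONFINITE
    t_end = t_end_steps * task.dt
    fitness = 0.0 if diverged else trial_fitness(
        r_final, r0, z, t_end, task, body, attacked=attacked)
    return TrialResult(r_final=float(r_final), r0=float(r0),
                       path_length=float(z), t_end=float(t_end),
                       attacked=attacked, fitness=float(fitness),
                       diverged=diverged, trajectory=trajectory)


def _reference_trial(params: NetworkParams, x0, on, bearing, r0,
                     task: TaskConfig, body_p: BodyParams,
                     terminate_on_attack: bool, record: bool):
    """Pure-Python trial loop assembled from the public ops; mirrors the
    compiled kernel step for step."""
    side = body_p.arena_side
    dt = task.dt
    x = x0.copy()
    body = BodyState(position=np.array([side / 2, side / 2]))
    zero = np.zeros(params.n_sensors)
    for _ in range(task.n_transient_steps):
        x = step_network(x, params, zero, dt)
        o1, o2 = neuron_output(x[:2], params.theta[:2])
        body = step_motor(body, o1, o2, body_p, dt)
        body, _ = step_kinematics(body, dt, side)

    ang = body.heading - bearing
    target = np.array([wrap_coord(body.position[0] + r0 * math.cos(ang), side),
                       wrap_coord(body.position[1] + r0 * math.sin(ang),
                                  side)])
    path = 0.0
    r = r0
    status = _kernels.STATUS_TIMEOUT
    t_end_steps = task.n_steps
    rows = [] if record else None
    for step in range(task.n_steps):
        raw = sensor_values(body, target, body_p)
        inputs = gate_perception(raw, bool(on[step]), body, body_p)
        x = step_network(x, params, np.array(inputs), dt)
        o1, o2 = neuron_output(x[:2], params.theta[:2])
        body = step_motor(body, o1, o2, body_p, dt)
        body, disp = step_kinematics(body, dt, side)
        path += disp
        r = toroidal_distance(body.position, target, side)
        if record:
            rows.append([(step + 1) * dt, body.position[0], body.position[1],
                         body.heading, body.velocity, body.turn_rate,
                         raw[0], raw[1], float(on[step]), inputs[0],
                         inputs[1], r, *x])
        if not np.isfinite(x).all() or not math.isfinite(r):
            status = _kernels.STATUS_NONFINITE
            t_end_steps = step + 1
            break
        if terminate_on_attack and r <= body_p.interaction_radius \
                and body.velocity <= body_p.perception_threshold:
            status = _kernels.STATUS_ATTACKED
            t_end_steps = step + 1
            break
    traj = np.array(rows) if record else None
    return r, path, t_end_steps, status, traj


def trajectory_to_csv(result: TrialResult, path) -> None:
    """Write a recorded trial trajectory as CSV (one row per Euler step;
    header names the recorded quantities, positions in arena units, angles
    in radians, time in simulation time units)."""
    if result.trajectory is None:
        raise ValueError("trial was run without record=True")
    n_neural = result.trajectory.shape[1] - len(TRAJECTORY_COLUMNS) + 5
    header = "step," + ",".join(TRAJECTORY_COLUMNS[:-5]) \
        + "".join(f",x{i + 1}" for i in range(n_neural))
    steps = np.arange(result.trajectory.shape[0])[:, None]
    np.savetxt(path, np.hstack([steps, result.trajectory]),
               delimiter=",", header=header, comments="", fmt="%.10g")


def evaluate_forager(params: NetworkParams, task: TaskConfig,
                     body: BodyParams, rng: np.random.Generator,
                     return_trials: bool = False):
    """Mean fitness over the bearing battery (one trial per bearing, fresh
    neural-state randomization, r0 draw, and schedule per trial)."""
    results = [run_trial(params, b, task, body, rng)
               for b in battery_bearings(task.n_bearings)]
    mean_f = float(np.mean([t.fitness for t in results]))
    if return_trials:
        return mean_f, results
    return mean_f
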