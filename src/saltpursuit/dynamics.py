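"""Post-evolution strategy analysis.

Four layers:

* **Equilibria** — multistart root finding on the CTRNN vector field at a
  fixed input level, with Jacobian-eigenvalue stability labels
  (stable / saddle / unstable).
* **Limit cycles / periodicity** — an evolved forager is a *periodic
  sampler* if, with no signal ever delivered, its velocity recurrently dips
  below the perceptual threshold phi with a regular inter-sample period
  (an intrinsic neural limit cycle expressed through the body).
* **Perturbation protocols** — paired simulations (one standard-length
  signal block vs. an identical no-signal null) quantify how signal changes
  movement.  Deceleration relative to the null is *signal listening*,
  acceleration is *signal chasing*.  Non-periodic foragers are measured by
  response duration and distance deltas; periodic foragers by changes in
  sample time, movement period, and distance over one period.
* **Census / robustness** — a forager's strategy label (listening /
  chasing / mixed) summarizes a grid of perturbations over target distance
  and bearing; the robustness map scores fitness over thousands of initial
  target positions inside the detection radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root as _scipy_root

from . import _kernels
from .body import BodyParams
from .network import NetworkParams, neuron_output
from .task import TaskConfig, battery_bearings, run_trial

__all__ = [
    "Equilibrium",
    "EquilibriumSet",
    "LimitCycle",
    "PerturbationRecord",
    "StrategyReport",
    "find_equilibria",
    "detect_limit_cycle",
    "classify_periodicity",
    "perturb_nonperiodic",
    "perturb_periodic",
    "classify_strategy",
    "strategy_report",
    "robustness_lattice",
    "robustness_map",
    "DEFAULT_PERTURBATION_DISTANCES",
]

RESIDUAL_TOL = 1e-8
DEDUPE_RADIUS = 1e-4
CYCLE_CV_TOL = 0.05
MIN_CYCLES = 5
BASELINE_RETURN_TOL = 0.01  # on motor-neuron states x1, x2
DEFAULT_PERTURBATION_DISTANCES = (5.0, 9.0, 13.0, 17.0, 21.0, 25.0)
PURITY_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# equilibria

@dataclass
class Equilibrium:
    x: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stability: str  # "stable" | "saddle" | "unstable"


@dataclass
class LimitCycle:
    period: float                # time units
    orbit: np.ndarray            # sampled states over one period (k, n)
    motor_orbit: np.ndarray      # motor outputs over one period (k, 2)


@dataclass
class EquilibriumSet:
    points: list
    limit_cycle: LimitCycle | None = None

    @property
    def n_stable(self) -> int:
        return sum(p.stability == "stable" for p in self.points)

    def to_text(self) -> str:
        """Human-readable summary: one line per fixed point (state,
        eigenvalues, stability label), plus the limit cycle if any."""
        lines = []
        for p in self.points:
            state = " ".join(f"{v:.6g}" for v in p.x)
            eig = " ".join(f"{e.real:.4g}{e.imag:+.4g}j"
                           for e in p.eigenvalues)
            lines.append(f"point [{state}] eig [{eig}] {p.stability}")
        if self.limit_cycle is not None:
            lines.append(f"limit_cycle period {self.limit_cycle.period:.6g}")
        return "\n".join(lines)


def _vector_field(params: NetworkParams, drive: np.ndarray):
    """Unscaled field f(x) = -x + W o(x) + drive (roots are unaffected by
    tau; stability is judged with the tau-scaled Jacobian)."""
    W = params.w_syn

    def f(x):
        return -x + W @ neuron_output(x, params.theta) + drive

    def jac(x):
        o = neuron_output(x, params.theta)
        return -np.eye(params.n_neurons) + W * (o * (1 - o))

    return f, jac


def _classify_stability(params: NetworkParams, x: np.ndarray, jac):
    J = jac(x) / params.tau[:, None]
    eig = np.linalg.eigvals(J)
    re = eig.real
    tol = 1e-9
    if np.all(re < -tol):
        label = "stable"
    elif np.all(re > tol):
        label = "unstable"
    else:
        label = "saddle"
    return eig, label


def _logit(p):
    return np.log(p / (1 - p))


def _multistart_points(params: NetworkParams, drive: np.ndarray,
                       n_random: int, rng: np.random.Generator):
    """Start states: preimages (x = theta + logit(o)) of an output-space
    lattice on the motor neurons with the remaining neurons at saturation
    corners — for small networks (n <= 2) the lattice covers every neuron —
    plus random draws from the box that must contain all fixed points."""
    n = params.n_neurons
    lattice = np.arange(0.05, 0.951, 0.15)
    lo = drive + np.minimum(params.w_syn, 0).sum(axis=1)
    hi = drive + np.maximum(params.w_syn, 0).sum(axis=1)
    starts = []
    if n <= 2:
        grids = np.meshgrid(*([lattice] * n), indexing="ij")
        outs = np.stack([g.ravel() for g in grids], axis=1)
        starts.append(params.theta + _logit(outs))
    else:
        corners = np.array([0.02, 0.98])
        motor = np.stack([g.ravel() for g in
                          np.meshgrid(lattice, lattice, indexing="ij")],
                         axis=1)
        rest_grids = np.meshgrid(*([corners] * (n - 2)), indexing="ij")
        rest = np.stack([g.ravel() for g in rest_grids], axis=1)
        for r_row in rest:
            outs = np.concatenate(
                [motor, np.tile(r_row, (motor.shape[0], 1))], axis=1)
            starts.append(params.theta + _logit(outs))
    starts.append(rng.uniform(lo - 0.5, hi + 0.5, (n_random, n)))
    return np.concatenate(starts, axis=0)


def find_equilibria(params: NetworkParams, input_level=(0.0, 0.0),
                    n_random_starts: int = 50,
                    seed: int = 0) -> EquilibriumSet:
    """Locate all fixed points of the network at a constant input level.

    Multistart hybrid-Powell root finding with the analytic Jacobian;
    solutions are kept when the residual infinity-norm is below 1e-8 and
    deduplicated within 1e-4 in state space.
    """
    drive = params.w_sens @ np.asarray(input_level, dtype=float)
    f, jac = _vector_field(params, drive)
    rng = np.random.default_rng(seed)
    roots: list[np.ndarray] = []
    for x0 in _multistart_points(params, drive, n_random_starts, rng):
        sol = _scipy_root(f, x0, jac=jac, method="hybr")
        if not sol.success:
            continue
        x = sol.x
        if np.max(np.abs(f(x))) > RESIDUAL_TOL:
            continue
        if any(np.linalg.norm(x - r) < DEDUPE_RADIUS for r in roots):
            continue
        roots.append(x)
    points = []
    for x in sorted(roots, key=lambda r: tuple(r)):
        eig, label = _classify_stability(params, x, jac)
        points.append(Equilibrium(x=x, residual=float(np.max(np.abs(f(x)))),
                                  eigenvalues=eig, stability=label))
    return EquilibriumSet(points=points)


# ---------------------------------------------------------------------------
# limit cycles and periodicity

def _regular_period(event_times: np.ndarray):
    """Mean interval and regularity check over the trailing intervals
    (coefficient of variation below 5% across at least 5 cycles)."""
    if event_times.size < MIN_CYCLES + 1:
        return None
    intervals = np.diff(event_times)[-10:]
    if intervals.size < MIN_CYCLES:
        return None
    mean = float(intervals.mean())
    if mean <= 0:
        return None
    cv = float(intervals.std() / mean)
    if cv >= CYCLE_CV_TOL:
        return None
    return mean


def detect_limit_cycle(params: NetworkParams, input_level=(0.0, 0.0),
                       dt: float = 0.05, transient: float = 400.0,
                       window: float = 800.0,
                       x0: np.ndarray | None = None) -> LimitCycle | None:
    """Detect a stable limit cycle of the isolated network by long
    integration past a transient.

    The summed motor output o1+o2 is monitored for upward mid-range
    crossings; a cycle is reported when at least 5 consecutive periods
    agree within a 5% coefficient of variation.  Returns ``None`` when the
    state converges to a point (or oscillates imperceptibly); irregular
    non-settling dynamics also return ``None`` (they are neither class).
    """
    n = params.n_neurons
    if x0 is None:
        x0 = np.full(n, 0.5)
    drive = params.w_sens @ np.asarray(input_level, dtype=float)
    n_trans = int(round(transient / dt))
    n_win = int(round(window / dt))
    pre = _kernels.integrate_network(np.asarray(x0, float), params.tau,
                                     params.theta, params.w_syn, drive,
                                     dt, n_trans)
    states = _kernels.integrate_network(pre[-1].copy(), params.tau,
                                        params.theta, params.w_syn, drive,
                                        dt, n_win)
    motor = neuron_output(states[:, 0], params.theta[0]) \
        + neuron_output(states[:, 1], params.theta[1])
    amp = motor.max() - motor.min()
    if amp < 1e-4:
        return None
    mid = 0.5 * (motor.max() + motor.min())
    above = motor > mid
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    period = _regular_period(crossings * dt)
    if period is None:
        return None
    k = int(round(period / dt))
    start = int(crossings[-1]) - k
    if start < 0:
        return None
    orbit = states[start:start + k]
    motor_orbit = np.stack(
        [neuron_output(orbit[:, 0], params.theta[0]),
         neuron_output(orbit[:, 1], params.theta[1])], axis=1)
    return LimitCycle(period=period, orbit=orbit, motor_orbit=motor_orbit)


def _sample_onsets(v: np.ndarray, phi: float, dt: float) -> np.ndarray:
    """Times at which velocity crosses down to <= phi (sampling onsets);
    a trace that starts at or below phi counts an onset at its first step."""
    low = v <= phi
    onsets = np.flatnonzero(low[1:] & ~low[:-1]) + 1
    if low.size and low[0]:
        onsets = np.concatenate(([0], onsets))
    return onsets * dt


def classify_periodicity(params: NetworkParams, task: TaskConfig,
                         body: BodyParams, rng: np.random.Generator,
                         n_init: int = 10) -> str:
    """Label the embodied agent's intrinsic (no-signal) behavior.

    ``"periodic"``: velocity recurrently dips below phi with a regular
    inter-sample period, from every random initial state tried.
    ``"nonperiodic"``: never (steady cruising, steady rest, or irregular
    sampling) from every initial state.  Disagreement across initial states
    is escalated as ``"irregular"`` and excluded from the two-way census.
    """
    silent = np.zeros(task.n_steps, dtype=np.uint8)
    labels = []
    for _ in range(n_init):
        res = run_trial(params, 0.0, task, body, rng, schedule=silent,
                        record=True, terminate_on_attack=False)
        v = res.trajectory[:, 4]
        onsets = _sample_onsets(v, body.perception_threshold, task.dt)
        # must actually alternate: dips below phi separated by movement
        period = _regular_period(onsets) if onsets.size else None
        labels.append("periodic" if period is not None else "nonperiodic")
    if all(l == labels[0] for l in labels):
        return labels[0]
    return "irregular"


# ---------------------------------------------------------------------------
# perturbation protocols

@dataclass
class PerturbationRecord:
    target_distance: float
    target_bearing: float
    mode: str                       # "nonperiodic" | "periodic"
    response_sign: str              # "listening" | "chasing" | "null"
    delta_distance: float
    response_duration: float | None = None   # nonperiodic mode
    delta_period: float | None = None        # periodic mode
    delta_sample_time: float | None = None   # periodic mode
    censored: bool = False


def _paired_runs(params: NetworkParams, task: TaskConfig, body: BodyParams,
                 distance: float, bearing: float, rng: np.random.Generator,
                 onset_step: int | None, block_steps: int):
    """Run a null (never-signaling) and a perturbed (single signal block)
    trial from identical initial state; returns both trajectories and the
    onset step.  ``onset_step=None`` defers onset to the caller (periodic
    protocol: the null is run first to locate the first sample)."""
    x0 = rng.uniform(0.0, 1.0, params.n_neurons)
    null_sched = np.zeros(task.n_steps, dtype=np.uint8)
    null = run_trial(params, bearing, task, body, rng, r0=distance, x0=x0,
                     schedule=null_sched, record=True,
                     terminate_on_attack=False)
    if onset_step is None:
        v = null.trajectory[:, 4]
        low = np.flatnonzero(v <= body.perception_threshold)
        if low.size == 0:
            return null, None, None  # never samples: misclassified agent
        onset_step = int(low[0])
    pert_sched = null_sched.copy()
    pert_sched[onset_step:onset_step + block_steps] = 1
    pert = run_trial(params, bearing, task, body, rng, r0=distance, x0=x0,
                     schedule=pert_sched, record=True,
                     terminate_on_attack=False)
    return null, pert, onset_step


def perturb_nonperiodic(params: NetworkParams, task: TaskConfig,
                        body: BodyParams, distance: float, bearing: float,
                        rng: np.random.Generator,
                        settle: float = 50.0) -> PerturbationRecord:
    """Signal-response probe for a non-periodic forager.

    A single signal block of the evolved length (s_P*T/s_I time units) is
    delivered after a settling period; the response window runs from signal
    onset to the first step where both motor-neuron states have returned to
    within 0.01 of their pre-onset values.  Deltas are measured against the
    paired no-signal null over the same window.
    """
    onset = int(round(settle / task.dt))
    null, pert, _ = _paired_runs(params, task, body, distance, bearing, rng,
                                 onset, task.block_steps)
    xm_null = null.trajectory[:, 12:14]
    xm_pert = pert.trajectory[:, 12:14]
    base = xm_pert[onset - 1]
    dev = np.max(np.abs(xm_pert[onset:] - base), axis=1)
    departed = np.flatnonzero(dev > BASELINE_RETURN_TOL)
    if departed.size == 0:
        return PerturbationRecord(distance, bearing, "nonperiodic", "null",
                                  0.0, response_duration=0.0)
    after = np.flatnonzero(dev[departed[0]:] <= BASELINE_RETURN_TOL)
    censored = after.size == 0
    end_rel = dev.size if censored else departed[0] + int(after[0])
    end = onset + end_rel
    duration = end_rel * task.dt
    v_null = null.trajectory[onset:end, 4]
    v_pert = pert.trajectory[onset:end, 4]
    delta_dist = float((v_pert.sum() - v_null.sum()) * task.dt)
    dv = float(v_pert.mean() - v_null.mean())
    sign = "null" if abs(dv) < 1e-9 else ("chasing" if dv > 0 else "listening")
    return PerturbationRecord(distance, bearing, "nonperiodic", sign,
                              delta_dist, response_duration=duration,
                              censored=censored)


def _periodic_measures(traj: np.ndarray, t_on: int, phi: float, dt: float):
    """(sample_time, period, distance, censored) from one recorded trace,
    measured from the sampling onset step ``t_on``."""
    v = traj[:, 4]
    above = np.flatnonzero(v[t_on:] > phi)
    if above.size == 0:
        return (v.size - t_on) * dt, None, 0.0, True
    sample_steps = int(above[0])
    low_again = np.flatnonzero(v[t_on + sample_steps:] <= phi)
    if low_again.size == 0:
        period_steps = v.size - t_on
        censored = True
    else:
        period_steps = sample_steps + int(low_again[0])
        censored = False
    dist = float(v[t_on:t_on + period_steps].sum() * dt)
    return sample_steps * dt, period_steps * dt, dist, censored


def perturb_periodic(params: NetworkParams, task: TaskConfig,
                     body: BodyParams, distance: float, bearing: float,
                     rng: np.random.Generator) -> PerturbationRecord | None:
    """Signal-response probe for a periodic sampler.

    The signal block is delivered the first time the agent samples
    (v <= phi) after the transient.  Measured against the paired null:
    change in sample time, in the movement period from onset to the next
    sample, and in distance traveled over that period.  Shorter sample +
    shorter period + less distance is chasing; the reverse is listening
    (majority vote over the three deltas, distance breaking ties).
    Returns ``None`` if the agent never samples (caller should re-route to
    the non-periodic protocol).
    """
    null, pert, onset = _paired_runs(params, task, body, distance, bearing,
                                     rng, None, task.block_steps)
    if pert is None:
        return None
    phi = body.perception_threshold
    s_n, p_n, d_n, cen_n = _periodic_measures(null.trajectory, onset, phi,
                                              task.dt)
    s_p, p_p, d_p, cen_p = _periodic_measures(pert.trajectory, onset, phi,
                                              task.dt)
    censored = cen_n or cen_p
    d_sample = s_p - s_n
    d_period = (p_p - p_n) if (p_p is not None and p_n is not None) else None
    d_dist = d_p - d_n
    tol = 1e-9
    votes = [x for x in (d_sample, d_period, d_dist) if x is not None]
    neg = sum(x < -tol for x in votes)
    pos = sum(x > tol for x in votes)
    if neg == pos == 0:
        sign = "null"
    elif neg != pos:
        sign = "chasing" if neg > pos else "listening"
    else:
        sign = "chasing" if d_dist < 0 else "listening"
    return PerturbationRecord(distance, bearing, "periodic", sign, d_dist,
                              delta_period=d_period,
                              delta_sample_time=d_sample, censored=censored)


def classify_strategy(records, purity: float = PURITY_THRESHOLD) -> str:
    """Label a perturbation grid: a pure label when at least 95% of the
    non-null records share one response sign, ``"mixed"`` otherwise, and
    ``"insensitive"`` when no record responds at all."""
    signs = [r.response_sign for r in records if r.response_sign != "null"]
    if not signs:
        return "insensitive"
    for label in ("listening", "chasing"):
        if sum(s == label for s in signs) / len(signs) >= purity:
            return label
    return "mixed"


@dataclass
class StrategyReport:
    periodicity: str
    label: str
    baseline: dict
    grid: list


def strategy_report(params: NetworkParams, task: TaskConfig,
                    body: BodyParams, rng: np.random.Generator,
                    distances=DEFAULT_PERTURBATION_DISTANCES,
                    bearings=None, n_init: int = 10) -> StrategyReport:
    """Full per-forager analysis: periodicity class, null-condition
    baseline, perturbation grid over distance x bearing, strategy label."""
    if bearings is None:
        bearings = battery_bearings(task.n_bearings)
    periodicity = classify_periodicity(params, task, body, rng,
                                       n_init=n_init)
    silent = np.zeros(task.n_steps, dtype=np.uint8)
    null = run_trial(params, 0.0, task, body, rng, schedule=silent,
                     record=True, terminate_on_attack=False)
    v = null.trajectory[:, 4]
    baseline: dict = {"mean_velocity": float(v.mean())}
    if periodicity == "periodic":
        onsets = _sample_onsets(v, body.perception_threshold, task.dt)
        period = _regular_period(onsets)
        baseline["period"] = period
        s, p, d, _ = _periodic_measures(
            null.trajectory, int(round(onsets[0] / task.dt)),
            body.perception_threshold, task.dt)
        baseline["sample_time"] = s
    grid = []
    use_periodic = periodicity == "periodic"
    for dist in distances:
        for b in bearings:
            if use_periodic:
                rec = perturb_periodic(params, task, body, dist, b, rng)
                if rec is None:
                    rec = perturb_nonperiodic(params, task, body, dist, b,
                                              rng)
            else:
                rec = perturb_nonperiodic(params, task, body, dist, b, rng)
            grid.append(rec)
    return StrategyReport(periodicity=periodicity,
                          label=classify_strategy(grid),
                          baseline=baseline, grid=grid)


# ---------------------------------------------------------------------------
# robustness map

def robustness_lattice(detection_radius: float = 29.0,
                       band=(23.0, 27.0), n_total: int = 5400,
                       n_band: int = 900, r_min: float = 2.0,
                       ring_spacing: float = 0.5):
    """Polar lattice of initial target positions inside the detection
    radius: concentric rings every 0.5 units with per-ring counts
    proportional to circumference, normalized separately inside and outside
    the trained annulus so exactly ``n_band`` points land inside it.
    Returns an (n_total, 2) array of (radius, angle) pairs.
    """
    radii = np.arange(r_min + ring_spacing / 2, detection_radius,
                      ring_spacing)
    in_band = (radii >= band[0]) & (radii <= band[1])

    def _allocate(rs, total):
        quota = total * rs / rs.sum()
        counts = np.floor(quota).astype(int)
        frac_order = np.argsort(-(quota - counts))
        counts[frac_order[:total - counts.sum()]] += 1
        return counts

    counts = np.empty(radii.size, dtype=int)
    counts[in_band] = _allocate(radii[in_band], n_band)
    counts[~in_band] = _allocate(radii[~in_band], n_total - n_band)
    golden = math.pi * (3 - math.sqrt(5))
    points = []
    for j, (r, c) in enumerate(zip(radii, counts)):
        angles = (j * golden + 2 * math.pi * np.arange(c) / c) \
            % (2 * math.pi)
        points.extend((r, a) for a in angles)
    return np.array(points)


def robustness_map(params: NetworkParams, task: TaskConfig,
                   body: BodyParams, rng: np.random.Generator,
                   lattice: np.ndarray | None = None,
                   n_headings: int = 5):
    """Mean fitness at every lattice position, averaged over ``n_headings``
    initial headings at 2*pi/5 spacing.  Returns ``(grid, summary)`` where
    grid rows are (radius, angle, mean_fitness) and the summary reports
    mean fitness and success fraction (F >= 1) inside and outside the
    trained annulus."""
    if lattice is None:
        lattice = robustness_lattice(body.detection_radius,
                                     (task.r0_min, task.r0_max))
    rows = np.empty((lattice.shape[0], 3))
    headings = 2 * math.pi * np.arange(n_headings) / n_headings
    for i, (r, ang) in enumerate(lattice):
        fits = []
        for h in headings:
            bearing = h - ang  # relative bearing seen from heading h
            res = run_trial(params, bearing, task, body, rng, r0=float(r))
            fits.append(res.fitness)
        rows[i] = (r, ang, float(np.mean(fits)))
    in_band = (rows[:, 0] >= task.r0_min) & (rows[:, 0] <= task.r0_max)
    summary = {
        "mean_fitness_trained": float(rows[in_band, 2].mean()),
        "mean_fitness_extrapolated": float(rows[~in_band, 2].mean()),
        "success_fraction_trained": float((rows[in_band, 2] >= 1).mean()),
        "success_fraction_extrapolated":
            float((rows[~in_band, 2] >= 1).mean()),
    }
    return rows, summary
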