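"""Compiled inner loops for trial simulation.

These numba kernels mirror, operation for operation, the pure-Python
reference path assembled from the public ops in ``network.py`` / ``body.py``
(the readable source of truth; a test asserts trajectory agreement).  They
exist because evolution runs integrate hundreds of thousands of trials.
The kernels carry the heading sine/cosine and the motor outputs from one
step to the next instead of recomputing them; recomputation is
deterministic, so this changes nothing numerically.

Per Euler step (dt = 0.05) the order is: raw sensors -> perceptual gating
-> network state update -> motor update (outputs from the *new* state) ->
heading then position integration -> attack-termination check.

Trajectory record layout (one row per trial step, post-update state):
  0 time, 1 x, 2 y, 3 heading, 4 velocity, 5 turn_rate, 6 s1, 7 s2,
  8 signal_on, 9 I1, 10 I2, 11 target distance, 12.. neural states.
"""

import math

import numpy as np
from numba import njit

TRAJ_BASE_COLS = 12

# trial status codes
STATUS_TIMEOUT = 0
STATUS_ATTACKED = 1
STATUS_NONFINITE = 2

_SIGMOID_SAT = 36.75  # 1/(1+e^-z) rounds to exactly 1.0 beyond this


@njit(cache=True)
def _sigmoid(z):
    if z > _SIGMOID_SAT:
        return 1.0
    if z >= 0.0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


@njit(cache=True)
def _wrap_angle(a):
    if a > math.pi:
        a -= 2.0 * math.pi
    elif a <= -math.pi:
        a += 2.0 * math.pi
    if a > math.pi or a <= -math.pi:  # arbitrary input fallback
        a = (a + math.pi) % (2.0 * math.pi) - math.pi
        if a == -math.pi:
            a = math.pi
    return a


@njit(cache=True)
def _wrap_coord(a, side):
    # one-period fold; per-step displacements never exceed one arena side
    if a >= side:
        return a - side
    if a < 0.0:
        return a + side
    return a


@njit(cache=True)
def _toro_dist(ax, ay, bx, by, side):
    # both points must already lie in [0, side)
    dx = abs(ax - bx)
    if dx > side / 2.0:
        dx = side - dx
    dy = abs(ay - by)
    if dy > side / 2.0:
        dy = side - dy
    return math.sqrt(dx * dx + dy * dy)


@njit(cache=True)
def simulate_trial(tau, theta, w_syn, w_sens, x_init, signal_on,
                   bearing, r0,
                   side, dt, n_transient, n_steps,
                   drag_eff, max_exertion, max_turn,
                   gain, offset, d_detect, lam, phi,
                   movement_dependent, terminate, record, traj):
    """Integrate one full trial; returns (r_final, path_length, t_end_steps,
    status).  ``drag_eff`` is the effective drag rate (f, or 1-f for the
    printed drag form).  ``traj`` must be (n_steps, 12+n) when ``record``."""
    n = tau.shape[0]
    x = x_init.copy()
    xn = np.empty(n)
    o = np.empty(n)

    px = side / 2.0
    py = side / 2.0
    heading = 0.0
    v = 0.0
    q = 0.0

    # transient: full dynamics, zero sensory input, no target
    for _ in range(n_transient):
        for j in range(n):
            o[j] = _sigmoid(x[j] - theta[j])
        for i in range(n):
            s = -x[i]
            for j in range(n):
                s += w_syn[i, j] * o[j]
            xn[i] = x[i] + (dt / tau[i]) * s
        for i in range(n):
            x[i] = xn[i]
        o1 = _sigmoid(x[0] - theta[0])
        o2 = _sigmoid(x[1] - theta[1])
        v = v + dt * (-v * drag_eff + (o1 + o2) * max_exertion)
        if v < 0.0:
            v = 0.0
        q = q + dt * ((o1 - o2) * max_turn - q)
        heading = _wrap_angle(heading + q * dt)
        px = _wrap_coord(px + v * dt * math.cos(heading), side)
        py = _wrap_coord(py + v * dt * math.sin(heading), side)

    # encounter: target placed relative to post-transient pose
    ang = heading - bearing
    tx = _wrap_coord(px + r0 * math.cos(ang), side)
    ty = _wrap_coord(py + r0 * math.sin(ang), side)

    path = 0.0
    r = r0
    t_end = n_steps
    status = STATUS_TIMEOUT
    half = offset / 2.0
    ch = math.cos(heading)
    sh = math.sin(heading)
    o1 = _sigmoid(x[0] - theta[0])
    o2 = _sigmoid(x[1] - theta[1])

    for step in range(n_steps):
        lx = _wrap_coord(px - half * sh, side)
        ly = _wrap_coord(py + half * ch, side)
        rx = _wrap_coord(px + half * sh, side)
        ry = _wrap_coord(py - half * ch, side)
        s1 = gain * (1.0 - _toro_dist(lx, ly, tx, ty, side) / d_detect)
        s2 = gain * (1.0 - _toro_dist(rx, ry, tx, ty, side) / d_detect)
        if s1 < 0.0:
            s1 = 0.0
        if s2 < 0.0:
            s2 = 0.0

        sig = signal_on[step]
        if sig == 0:
            i1 = 0.0
            i2 = 0.0
        elif movement_dependent and v > phi:
            i1 = 0.0
            i2 = 0.0
        else:
            i1 = s1
            i2 = s2

        o[0] = o1  # outputs of the pre-update state, carried from last step
        o[1] = o2
        for j in range(2, n):
            o[j] = _sigmoid(x[j] - theta[j])
        for i in range(n):
            s = -x[i]
            for j in range(n):
                s += w_syn[i, j] * o[j]
            s += w_sens[i, 0] * i1 + w_sens[i, 1] * i2
            xn[i] = x[i] + (dt / tau[i]) * s
        for i in range(n):
            x[i] = xn[i]

        o1 = _sigmoid(x[0] - theta[0])
        o2 = _sigmoid(x[1] - theta[1])
        v = v + dt * (-v * drag_eff + (o1 + o2) * max_exertion)
        if v < 0.0:
            v = 0.0
        q = q + dt * ((o1 - o2) * max_turn - q)
        heading = _wrap_angle(heading + q * dt)
        ch = math.cos(heading)
        sh = math.sin(heading)
        px = _wrap_coord(px + v * dt * ch, side)
        py = _wrap_coord(py + v * dt * sh, side)
        path += v * dt
        r = _toro_dist(px, py, tx, ty, side)

        if record:
            traj[step, 0] = (step + 1) * dt
            traj[step, 1] = px
            traj[step, 2] = py
            traj[step, 3] = heading
            traj[step, 4] = v
            traj[step, 5] = q
            traj[step, 6] = s1
            traj[step, 7] = s2
            traj[step, 8] = sig
            traj[step, 9] = i1
            traj[step, 10] = i2
            traj[step, 11] = r
            for i in range(n):
                traj[step, TRAJ_BASE_COLS + i] = x[i]

        if v != v or r != r:  # NaN: diverged dynamics
            status = STATUS_NONFINITE
            t_end = step + 1
            break
        if terminate and r <= lam and v <= phi:
            status = STATUS_ATTACKED
            t_end = step + 1
            break

    return r, path, t_end, status


@njit(cache=True)
def evaluate_population_kernel(taus, thetas, w_syns, w_senss,
                               x0s, r0s, bearings, schedules,
                               side, dt, n_transient, n_steps,
                               drag_eff, max_exertion, max_turn,
                               gain, offset, d_detect, lam, phi,
                               movement_dependent):
    """Run the full trial battery for a population.

    Shapes: taus (P, n), x0s (P, B, n), r0s (P, B), bearings (B,),
    schedules (P, B, n_steps) uint8.  Returns (P, B, 4) of
    (r_final, path_length, t_end_steps, status).
    """
    P = taus.shape[0]
    B = bearings.shape[0]
    out = np.empty((P, B, 4))
    dummy = np.empty((1, 1))
    for p in range(P):
        for t in range(B):
            r, z, t_end, status = simulate_trial(
                taus[p], thetas[p], w_syns[p], w_senss[p],
                x0s[p, t], schedules[p, t], bearings[t], r0s[p, t],
                side, dt, n_transient, n_steps,
                drag_eff, max_exertion, max_turn,
                gain, offset, d_detect, lam, phi,
                movement_dependent, True, False, dummy)
            out[p, t, 0] = r
            out[p, t, 1] = z
            out[p, t, 2] = t_end
            out[p, t, 3] = status
    return out


@njit(cache=True)
def integrate_network(x_init, tau, theta, w_syn, drive, dt, n_steps):
    """Integrate the network alone under constant per-neuron drive
    (``drive = w_sens @ I``); returns the (n_steps, n) state trajectory."""
    n = tau.shape[0]
    x = x_init.copy()
    o = np.empty(n)
    xn = np.empty(n)
    out = np.empty((n_steps, n))
    for step in range(n_steps):
        for j in range(n):
            o[j] = _sigmoid(x[j] - theta[j])
        for i in range(n):
            s = -x[i] + drive[i]
            for j in range(n):
                s += w_syn[i, j] * o[j]
            xn[i] = x[i] + (dt / tau[i]) * s
        for i in range(n):
            x[i] = xn[i]
            out[step, i] = x[i]
    return out
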