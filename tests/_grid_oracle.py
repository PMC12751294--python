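"""Independent fixed-point oracle for small (1- or 2-neuron) CTRNNs.

Brute-force bracketing, no Newton/quasi-Newton steps: the vector field is
evaluated on a dense grid over the box that must contain every fixed point
(each state coordinate of a fixed point equals drive plus a convex
combination of synaptic weights), candidate cells where every field
component changes sign across the cell are refined by recursive
subdivision, and nearby candidates are merged.  This is deliberately a
different algorithm from the package's multistart root finder so the two
can disagree when either is wrong.
"""

import numpy as np


def _sigma(x, theta):
    return 1.0 / (1.0 + np.exp(np.clip(theta - x, -500, 500)))


def _field(x1, x2, W, theta, drive):
    o1 = _sigma(x1, theta[0])
    o2 = _sigma(x2, theta[1])
    f1 = -x1 + W[0, 0] * o1 + W[0, 1] * o2 + drive[0]
    f2 = -x2 + W[1, 0] * o1 + W[1, 1] * o2 + drive[1]
    return f1, f2


def _state_box(W, drive, margin=0.5):
    lo = drive + np.minimum(W, 0).sum(axis=1) - margin
    hi = drive + np.maximum(W, 0).sum(axis=1) + margin
    return lo, hi


def grid_roots_1d(a, theta, drive, n_grid=20001, tol=1e-12):
    """All roots of -x + a*sigma(x, theta) + drive by dense sign-change
    scan plus bisection."""
    lo = drive + min(a, 0.0) - 0.5
    hi = drive + max(a, 0.0) + 0.5
    xs = np.linspace(lo, hi, n_grid)
    fs = -xs + a * _sigma(xs, theta) + drive
    roots = []
    sign_change = np.flatnonzero(np.sign(fs[:-1]) * np.sign(fs[1:]) < 0)
    for i in sign_change:
        a_, b_ = xs[i], xs[i + 1]
        fa = fs[i]
        while b_ - a_ > tol:
            m = 0.5 * (a_ + b_)
            fm = -m + a * _sigma(m, theta) + drive
            if fa * fm <= 0:
                b_ = m
            else:
                a_, fa = m, fm
        roots.append(0.5 * (a_ + b_))
    for i in np.flatnonzero(fs == 0.0):
        roots.append(xs[i])
    return sorted(roots)


def _cell_has_crossing(c1, c2):
    """Sign change of both field components across a cell's corner values
    (c1, c2 are length-4 corner arrays)."""
    return (c1.min() <= 0 <= c1.max()) and (c2.min() <= 0 <= c2.max())


def _refine(x_lo, x_hi, y_lo, y_hi, W, theta, drive, depth):
    xs = np.array([x_lo, x_hi, x_lo, x_hi])
    ys = np.array([y_lo, y_lo, y_hi, y_hi])
    f1, f2 = _field(xs, ys, W, theta, drive)
    if not _cell_has_crossing(f1, f2):
        return []
    if depth == 0 or (x_hi - x_lo) < 1e-10:
        return [(0.5 * (x_lo + x_hi), 0.5 * (y_lo + y_hi))]
    xm = 0.5 * (x_lo + x_hi)
    ym = 0.5 * (y_lo + y_hi)
    out = []
    for a, b in ((x_lo, xm), (xm, x_hi)):
        for c, d in ((y_lo, ym), (ym, y_hi)):
            out.extend(_refine(a, b, c, d, W, theta, drive, depth - 1))
    return out


def grid_roots_2d(W, theta, drive, n_grid=801, depth=22, merge_radius=1e-3):
    """All fixed points of the 2-neuron system by dense grid bracketing and
    recursive cell subdivision; returns an (k, 2) array."""
    W = np.asarray(W, float)
    theta = np.asarray(theta, float)
    drive = np.asarray(drive, float)
    lo, hi = _state_box(W, drive)
    xs = np.linspace(lo[0], hi[0], n_grid)
    ys = np.linspace(lo[1], hi[1], n_grid)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    F1, F2 = _field(X, Y, W, theta, drive)

    def cross(F):
        # sign change across any pair of cell corners
        pos = F > 0
        neg = F < 0
        zero = F == 0
        any_pos = pos[:-1, :-1] | pos[1:, :-1] | pos[:-1, 1:] | pos[1:, 1:]
        any_neg = neg[:-1, :-1] | neg[1:, :-1] | neg[:-1, 1:] | neg[1:, 1:]
        any_zero = zero[:-1, :-1] | zero[1:, :-1] | zero[:-1, 1:] \
            | zero[1:, 1:]
        return (any_pos & any_neg) | any_zero

    candidates = np.argwhere(cross(F1) & cross(F2))
    found = []
    for i, j in candidates:
        found.extend(_refine(xs[i], xs[i + 1], ys[j], ys[j + 1],
                             W, theta, drive, depth))
    # merge clusters (roots on shared cell edges appear twice)
    merged = []
    for pt in sorted(found):
        if not any(np.hypot(pt[0] - m[0], pt[1] - m[1]) < merge_radius
                   for m in merged):
            merged.append(pt)
    return np.array(merged)


def stability_label(x, W, theta, tau, drive):
    """Stability from the tau-scaled Jacobian eigenvalues (closed form)."""
    x = np.atleast_1d(np.asarray(x, float))
    n = x.size
    W = np.asarray(W, float).reshape(n, n)
    o = _sigma(x, np.asarray(theta, float))
    J = (-np.eye(n) + W * (o * (1 - o))) / np.asarray(tau, float)[:, None]
    re = np.linalg.eigvals(J).real
    if np.all(re < -1e-9):
        return "stable"
    if np.all(re > 1e-9):
        return "unstable"
    return "saddle"
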