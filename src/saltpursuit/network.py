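"""Continuous-time recurrent neural network (CTRNN) core.

The forager nervous system is a fully connected 5-node CTRNN with 2 sensors.
Each node's state :math:`x_i` evolves as

.. math::

    \\tau_i \\dot x_i = -x_i + \\sum_j a_{ij}\\,\\sigma(x_j, \\theta_j)
                       + \\sum_k b_{ik} I_k(t)

where :math:`\\sigma(x, \\theta) = 1/(1 + e^{\\theta - x})` is the node's
firing-rate output, constrained to (0, 1).  Integration is explicit forward
Euler at a fixed step (``dt = 0.05`` by default throughout the package);
adaptive stepping would change trajectories and is deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "NetworkParams",
    "neuron_output",
    "step_network",
    "equilibrate",
    "N_NEURONS",
    "N_SENSORS",
]

N_NEURONS = 5
N_SENSORS = 2

# Phenotypic ranges (symmetric weight/bias boxes; tau is mapped to [0.5, 16]
# by the genotype-phenotype map, see evolution.genome_to_phenotype).
THETA_RANGE = 16.0
SYN_RANGE = 16.0
SENS_RANGE = 20.0
TAU_MIN, TAU_MAX = 0.5, 16.0


@dataclass
class NetworkParams:
    """Phenotypic parameters of a CTRNN.

    Attributes
    ----------
    tau : (n,) array
        Per-neuron time constants, strictly positive (simulation time units).
    theta : (n,) array
        Per-neuron biases (dimensionless).
    w_syn : (n, n) array
        Synaptic weights, ``w_syn[i, j]`` from neuron *j* to neuron *i*.
    w_sens : (n, s) array
        Sensor weights, ``w_sens[i, k]`` from sensor *k* to neuron *i*.
    """

    tau: np.ndarray
    theta: np.ndarray
    w_syn: np.ndarray
    w_sens: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.w_syn = np.asarray(self.w_syn, dtype=float)
        self.w_sens = np.asarray(self.w_sens, dtype=float)
        n = self.tau.shape[0]
        if self.theta.shape != (n,):
            raise ValueError("theta length must match tau")
        if self.w_syn.shape != (n, n):
            raise ValueError(f"w_syn must be ({n},{n}), got {self.w_syn.shape}")
        if self.w_sens.ndim != 2 or self.w_sens.shape[0] != n:
            raise ValueError("w_sens must be (n_neurons, n_sensors)")
        if not np.all(self.tau > 0):
            raise ValueError("all time constants must be strictly positive")

    @property
    def n_neurons(self) -> int:
        return self.tau.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.w_sens.shape[1]


def neuron_output(x, theta):
    """Sigmoid firing rate ``1 / (1 + exp(theta - x))``.

    Computed in a branch-stable form (``scipy.special.expit``) so extreme
    states saturate cleanly to 0.0 / 1.0 instead of overflowing.
    Strictly increasing in ``x``; equals 0.5 at ``x == theta``.
    """
    return expit(np.asarray(x, dtype=float) - theta)


def step_network(x, params: NetworkParams, inputs, dt: float):
    """One forward-Euler step of the CTRNN state equation.

    Parameters
    ----------
    x : (n,) array
        Current neural state.
    inputs : (s,) array
        Per-sensor drive ``I_k`` (already gain-scaled sensor values).
    dt : float
        Time increment, > 0.

    Returns the new state array (the input array is not modified).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape[0] != params.n_sensors:
        raise ValueError("inputs length must equal n_sensors")
    o = neuron_output(x, params.theta)
    dx = -x + params.w_syn @ o + params.w_sens @ inputs
    return x + (dt / params.tau) * dx


def equilibrate(x, params: NetworkParams, dt: float, duration: float):
    """Integrate the network with zero sensory input for ``duration``.

    Trials begin with randomized states; running the network for a transient
    ``T_T`` (default 100 time units) lets it settle onto its intrinsic
    attractor before the encounter starts.  ``duration = 0`` returns the
    state unchanged.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    x = np.asarray(x, dtype=float).copy()
    zero = np.zeros(params.n_sensors)
    n_steps = int(round(duration / dt))
    for _ in range(n_steps):
        x = step_network(x, params, zero, dt)
    return x
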