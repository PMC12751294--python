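"""Hand-built fixture foragers.

Two synthetic genomes exercise the analysis suite without running
evolution:

* ``cruiser_genome`` — zero weights, motor biases at -1, so both motor
  outputs sit near 0.73 and the body cruises at constant speed in a
  straight line (a non-periodic, signal-insensitive baseline).
* ``periodic_sampler_genome`` — a classic two-neuron CTRNN oscillator on
  the hidden neurons drives both motor neurons through a high threshold,
  so motor output (and hence velocity) alternates between saturated-on and
  effectively off.  Velocity regularly decays below the perceptual
  threshold: a periodic sampler by construction.
"""

from __future__ import annotations

import numpy as np

from .network import NetworkParams
from .evolution import genome_to_phenotype, phenotype_to_genome

__all__ = ["cruiser_params", "cruiser_genome",
           "periodic_sampler_params", "periodic_sampler_genome"]


def cruiser_params() -> NetworkParams:
    tau = np.ones(5)
    theta = np.zeros(5)
    theta[:2] = -1.0  # motor outputs ~0.73 at the zero-state fixed point
    return NetworkParams(tau=tau, theta=theta,
                         w_syn=np.zeros((5, 5)), w_sens=np.zeros((5, 2)))


def cruiser_genome() -> np.ndarray:
    return phenotype_to_genome(cruiser_params())


def periodic_sampler_params(tau_osc: float = 2.0) -> NetworkParams:
    """Oscillator (neurons 3-4, mutually coupled with self-excitation)
    gating both motors (neurons 1-2) through a +10 bias threshold.
    ``tau_osc`` stretches the oscillation period proportionally."""
    tau = np.array([0.5, 0.5, tau_osc, tau_osc, 1.0])
    theta = np.array([10.0, 10.0, 2.75, 1.75, 0.0])
    w = np.zeros((5, 5))
    w[2, 2] = 4.5
    w[3, 3] = 4.5
    w[2, 3] = 1.0
    w[3, 2] = -1.0
    w[0, 2] = 16.0   # oscillator output drives both motors hard
    w[1, 2] = 16.0
    return NetworkParams(tau=tau, theta=theta, w_syn=w,
                         w_sens=np.zeros((5, 2)))


def periodic_sampler_genome() -> np.ndarray:
    return phenotype_to_genome(periodic_sampler_params())
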