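"""Real-valued generational genetic algorithm over CTRNN genomes.

A genome is 45 genes in [-1, 1], ordered [tau x5, theta x5, synaptic
weights x25 (to-neuron major), sensor weights x10 (to-neuron major)], mapped
linearly to phenotype: theta = 16 g, a = 16 g, b = 20 g, and
tau = 0.5 + 15.5 |g| (time constants must be positive; the magnitude map
keeps them in [0.5, 16], comfortably above the Euler step).

Each generation: every genome is scored as its mean fitness over the
24-bearing trial battery (fresh trial randomness every generation, so
measured fitness is noisy); the top 2% (the elite) pass unchanged; 1% of
the next generation are crossover children of two distinct elites
(contiguous half-genome swap at the midpoint); the remainder are elite
copies with every gene perturbed by U[-0.12, 0.12], clipped to [-1, 1].
The initial population is near-neutral (genes ~ U[-0.01, 0.01]) except the
motor-neuron biases, set so the phenotypic bias is -1 — a mildly movement-
suppressed start that helps movement-dependent conditions discover
stop-and-sample behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .network import NetworkParams
from .task import TaskConfig, battery_bearings, draw_schedule_offsets, \
    offsets_to_schedule, trial_fitness
from .body import BodyParams

__all__ = [
    "GENOME_LENGTH",
    "EvolutionConfig",
    "EvolutionResult",
    "genome_to_phenotype",
    "phenotype_to_genome",
    "init_population",
    "next_generation",
    "evaluate_population",
    "run_evolution",
]

N = 5
N_SENS = 2
GENOME_LENGTH = N + N + N * N + N * N_SENS  # 45
_TAU = slice(0, 5)
_THETA = slice(5, 10)
_SYN = slice(10, 35)
_SENS = slice(35, 45)
MOTOR_BIAS_GENES = (5, 6)

THETA_SCALE = 16.0
SYN_SCALE = 16.0
SENS_SCALE = 20.0
TAU_MIN, TAU_SPAN = 0.5, 15.5


@dataclass
class EvolutionConfig:
    population_size: int = 400
    generations: int = 1000
    mutation_variance: float = 0.12  # max per-gene change per generation
    elitism_fraction: float = 0.02
    crossover_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.elitism_fraction <= 1
                and 0 <= self.crossover_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.mutation_variance < 0 or self.mutation_variance > 2:
            raise ValueError("mutation_variance out of range")
        if self.n_elite < 1:
            raise ValueError("population too small for the elite fraction")

    @property
    def n_elite(self) -> int:
        return max(1, int(round(self.elitism_fraction * self.population_size)))

    @property
    def n_crossover(self) -> int:
        return int(round(self.crossover_fraction * self.population_size))


@dataclass
class EvolutionResult:
    best_fitness_per_generation: np.ndarray
    mean_fitness_per_generation: np.ndarray
    best_genome: np.ndarray
    best_fitness: float
    final_population: np.ndarray
    final_fitnesses: np.ndarray
    log: list


def _check_genes(genes: np.ndarray) -> np.ndarray:
    genes = np.asarray(genes, dtype=float)
    if genes.shape[-1] != GENOME_LENGTH:
        raise ValueError(f"genome must have {GENOME_LENGTH} genes, "
                         f"got {genes.shape[-1]}")
    if np.any(np.abs(genes) > 1.0):
        raise ValueError("genes must lie in [-1, 1]")
    return genes


def genome_arrays(genomes: np.ndarray):
    """Vectorized genotype->phenotype map.  ``genomes`` may have leading
    batch dimensions; returns (tau, theta, w_syn, w_sens) arrays."""
    g = _check_genes(genomes)
    tau = TAU_MIN + TAU_SPAN * np.abs(g[..., _TAU])
    theta = THETA_SCALE * g[..., _THETA]
    w_syn = SYN_SCALE * g[..., _SYN].reshape(g.shape[:-1] + (N, N))
    w_sens = SENS_SCALE * g[..., _SENS].reshape(g.shape[:-1] + (N, N_SENS))
    return tau, theta, w_syn, w_sens


def genome_to_phenotype(genes: np.ndarray) -> NetworkParams:
    """Translate one genome into CTRNN parameters (rejects out-of-range
    genes)."""
    tau, theta, w_syn, w_sens = genome_arrays(np.asarray(genes))
    return NetworkParams(tau=tau, theta=theta, w_syn=w_syn, w_sens=w_sens)


def phenotype_to_genome(params: NetworkParams) -> np.ndarray:
    """Inverse map (choosing the non-negative tau gene branch).  Exact
    round-trip on theta and weights; tau genes come back non-negative."""
    g = np.empty(GENOME_LENGTH)
    g[_TAU] = (params.tau - TAU_MIN) / TAU_SPAN
    g[_THETA] = params.theta / THETA_SCALE
    g[_SYN] = (params.w_syn / SYN_SCALE).ravel()
    g[_SENS] = (params.w_sens / SENS_SCALE).ravel()
    return _check_genes(g)


def init_population(config: EvolutionConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Near-neutral seeding: genes ~ U[-0.01, 0.01], motor biases fixed at
    phenotype -1 (gene -1/16)."""
    pop = rng.uniform(-0.01, 0.01, (config.population_size, GENOME_LENGTH))
    pop[:, MOTOR_BIAS_GENES] = -1.0 / THETA_SCALE
    return pop


def next_generation(population: np.ndarray, fitnesses: np.ndarray,
                    config: EvolutionConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Breed the next generation by rank: elites verbatim, a crossover
    sliver, and uniformly mutated elite copies for the rest."""
    population = _check_genes(population)
    P = population.shape[0]
    if P != config.population_size or len(fitnesses) != P:
        raise ValueError("population/fitness size mismatch with config")
    n_elite = config.n_elite
    if P < n_elite:
        raise ValueError("population smaller than elite count")
    order = np.argsort(-np.asarray(fitnesses, dtype=float), kind="stable")
    elites = population[order[:n_elite]]

    new = np.empty_like(population)
    new[:n_elite] = elites

    n_cross = config.n_crossover if n_elite >= 2 else 0
    half = GENOME_LENGTH // 2
    for c in range(n_cross):
        i, j = rng.choice(n_elite, size=2, replace=False)
        child = elites[i].copy()
        child[half:] = elites[j, half:]
        new[n_elite + c] = child

    n_mut = P - n_elite - n_cross
    parents = elites[rng.integers(0, n_elite, n_mut)]
    deltas = rng.uniform(-config.mutation_variance, config.mutation_variance,
                         (n_mut, GENOME_LENGTH))
    new[n_elite + n_cross:] = np.clip(parents + deltas, -1.0, 1.0)
    return new


def evaluate_population(population: np.ndarray, task: TaskConfig,
                        body: BodyParams, rng: np.random.Generator):
    """Score every genome on the full trial battery; returns per-genome mean
    fitness (diverged trials score 0)."""
    population = _check_genes(np.atleast_2d(population))
    P = population.shape[0]
    B = task.n_bearings
    tau, theta, w_syn, w_sens = genome_arrays(population)
    x0s = rng.uniform(0.0, 1.0, (P, B, N))
    r0s = rng.uniform(task.r0_min, task.r0_max, (P, B))
    if task.signal_reliable:
        schedules = np.ones((P, B, task.n_steps), dtype=np.uint8)
    else:
        offsets = draw_schedule_offsets(task, rng, size=(P, B))
        schedules = offsets_to_schedule(offsets, task)
    bearings = battery_bearings(B)
    drag_eff = (1 - body.drag) if body.printed_drag_form else body.drag
    raw = _kernels.evaluate_population_kernel(
        tau, theta, w_syn, w_sens, x0s, r0s, bearings, schedules,
        body.arena_side, task.dt, task.n_transient_steps, task.n_steps,
        drag_eff, body.max_exertion, body.max_turn,
        body.sensor_gain, body.sensor_offset, body.detection_radius,
        body.interaction_radius, body.perception_threshold,
        body.movement_dependent)

    fits = np.empty((P, B))
    for p in range(P):
        for t in range(B):
            r_f, z, t_end_steps, status = raw[p, t]
            if status == _kernels.STATUS_NONFINITE:
                fits[p, t] = 0.0
            else:
                fits[p, t] = trial_fitness(
                    r_f, r0s[p, t], z, t_end_steps * task.dt, task, body,
                    attacked=status == _kernels.STATUS_ATTACKED)
    return fits.mean(axis=1)


def run_evolution(config: EvolutionConfig, task: TaskConfig,
                  body: BodyParams, master_seed: int,
                  progress: bool = False) -> EvolutionResult:
    """Run the full generational loop; bitwise reproducible for a given
    master seed (all randomness flows from one SeedSequence)."""
    ss = np.random.SeedSequence(master_seed)
    rng_init, rng_ga, rng_eval = (np.random.default_rng(s)
                                  for s in ss.spawn(3))
    pop = init_population(config, rng_init)
    best_series = np.empty(config.generations)
    mean_series = np.empty(config.generations)
    log = []
    fitnesses = None
    for gen in range(config.generations):
        fitnesses = evaluate_population(pop, task, body, rng_eval)
        best_idx = int(np.argmax(fitnesses))
        best_series[gen] = fitnesses[best_idx]
        mean_series[gen] = fitnesses.mean()
        log.append({"generation": gen,
                    "mean_fitness": float(mean_series[gen]),
                    "best_fitness": float(best_series[gen]),
                    "best_index": best_idx})
        if progress and (gen % 10 == 0 or gen == config.generations - 1):
            print(f"gen {gen:4d}  mean F {mean_series[gen]:7.3f}  "
                  f"best F {best_series[gen]:7.3f}")
        if gen < config.generations - 1:
            pop = next_generation(pop, fitnesses, config, rng_ga)
    best_idx = int(np.argmax(fitnesses))
    return EvolutionResult(
        best_fitness_per_generation=best_series,
        mean_fitness_per_generation=mean_series,
        best_genome=pop[best_idx].copy(),
        best_fitness=float(fitnesses[best_idx]),
        final_population=pop,
        final_fitnesses=np.asarray(fitnesses),
        log=log)
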