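# saltpursuit

Evolvable saltatory pursuit of cryptic, stationary targets.

Many foragers face a pursuit problem that standard cruise/ambush models
skip: after an encounter, the target's signal may be intermittent
(unreliable), and the forager's own motion may block its perception
(think whisking, sniffing, or electrolocation — senses that require
slowing or stopping).  `saltpursuit` implements a minimal embodied model
of this problem: point-mass foragers driven by small continuous-time
recurrent neural networks (CTRNNs) pursue a stationary target in a
toroidal arena, a real-valued genetic algorithm evolves pursuit
strategies under four signal regimes, and a dynamical-analysis suite
classifies what evolved.

## The model

**Nervous system.**  A fully connected 5-node CTRNN with 2 sensors:

    tau_i dx_i/dt = -x_i + sum_j a_ij * sigma(x_j, theta_j) + sum_k b_ik I_k(t)
    sigma(x, theta) = 1 / (1 + e^(theta - x))

integrated by forward Euler at dt = 0.05.  Nodes 1 and 2 are the motor
neurons.

**Body.**  Velocity v and turn rate q follow

    dv/dt = -v f + (o1 + o2) delta        (top speed 2 delta / f ~ 4.44)
    dq/dt = (o1 - o2) eps - q

with drag f = 0.9, maximum exertion delta = 2, maximum angular velocity
eps = pi/6.  Two sensors sit at +-o/2 perpendicular to the heading
(o = 2); each reads gamma (1 - dist/d) of its toroidal distance to the
target (gamma = 3, detection radius d = 29), clamped at zero beyond d.

**Task.**  A trial runs T = 600 time units after a T_T = 100 transient;
the target appears at r0 ~ U[23, 27] at a bearing in [-pi/2, pi/2].  The
trial ends early only by "attack": within the interaction radius
lambda = 2 *and* stopped (v <= phi = 0.01).  Fitness is a chemotaxis
index with efficiency bonuses on capture:

    F = 0                                        r_n > d
    F = 1 - r_n/r0                               d >= r_n >= lambda
    F = (1 - r_n/r0) + r0/z + (1 - t_n/T)        r_n <= lambda

Four signal regimes cross reliability (R: always signaling; U: signal
for a fraction s_P = 0.3 of each of s_I = 20 intervals, at random
offsets) with movement dependence (I: perception always works; D: a
forager moving faster than phi perceives nothing — it must stop to
"sample").

**Evolution.**  Genomes are 45 genes in [-1, 1] mapped linearly to
CTRNN parameters; a generational GA (population 400, 1000 generations
at full scale) ranks foragers by mean fitness over a 24-bearing trial
battery, copies the top 2% verbatim, builds 1% of the next generation
as half-genome crossovers of two elites, and fills the rest with elite
copies mutated per-gene by U[-0.12, 0.12].

**Analysis.**  Evolved strategies are classified by (i) intrinsic
periodicity — does velocity dip below phi on a regular period with no
signal at all (a neural limit cycle expressed as stop-and-go, or
*periodic sampling*)? — and (ii) paired perturbation experiments: one
standard-length signal block versus an identical no-signal null.
Signal-triggered deceleration is *signal listening*, acceleration is
*signal chasing*; a grid of perturbations over target distance and
bearing yields a listening / chasing / mixed label per forager.

## Worked example

Evolve a small reliable-signal population and classify a fixture forager:

```sh
$ saltpursuit evolve --condition RI --seed 1 --pop 60 --generations 100 \
      --quiet --out out/ri1
condition RI  seed 1  final best F = 0.837  -> out/ri1

$ saltpursuit demo --seed 2 --out out/demo
cruiser: periodicity=nonperiodic strategy=insensitive -> out/demo/cruiser.json
periodic_sampler: periodicity=periodic strategy=insensitive -> out/demo/periodic_sampler.json
```

The evolve run writes `evolution_log.csv` (per-generation mean and best
fitness) and `best_genome.json`.  A best fitness near 1 means the
forager closes most of the initial 23-27 unit gap on every bearing;
values above 1 require actual captures (the attack bonuses).  The demo
genomes are hand-built negative controls: a constant-speed cruiser and
an intrinsic oscillator that stops to sample every ~58 time units —
neither has sensor weights, so both are correctly labelled insensitive
to signal.

Evaluate, perturb, and map any saved genome:

```sh
saltpursuit evaluate   --genome out/ri1/best_genome.json --seed 3 --out out/eval
saltpursuit classify   --genome out/ri1/best_genome.json --seed 3 --out out/cls
saltpursuit robustness --genome out/ri1/best_genome.json --seed 3 --out out/rob
```

`classify` writes the perturbation grid (6 target distances x 24
bearings) and the strategy report; `robustness` scores mean fitness at
5400 initial target positions inside the detection radius (900 inside
the trained 23-27 annulus), each averaged over 5 initial headings.

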