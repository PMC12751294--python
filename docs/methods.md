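# Methods

This note documents the model implemented by `saltpursuit`, the choices
made where the design was genuinely open, and what the test suite does
and does not establish.

## Model summary and assumptions

A point forager moves in a wrap-around square arena (side L = 100,
chosen so that the largest trained target distance, 27, stays well
under L/2 and the minimal-image toroidal metric is unambiguous; the
model only requires L greater than the detection radius).  The forager
is controlled by a fully connected 5-node CTRNN with two sensors; only
nodes 1 and 2 (the motor neurons) act on the body.  The target is
stationary and featureless except for its signal.  There is no
collision physics, no energy budget beyond the fitness bonuses, and no
co-adaptation of the target.

State order within one Euler step (dt = 0.05 everywhere): raw sensors
-> perceptual gating -> network state update -> motor update using the
*updated* motor-neuron outputs -> heading, then position -> attack
check.  The transient (T_T = 100) integrates the full dynamics
(network and body) with zero sensory input; the target is placed
relative to the pose at transient end, and path-length accounting
starts at the encounter.

## Parameters

| group | parameter | symbol | default | units |
|---|---|---|---|---|
| task | trial duration | T | 600 | time units |
| task | transient | T_T | 100 | time units |
| task | Euler step | dt | 0.05 | time units |
| task | initial target distance | r0 | U[23, 27] | arena units |
| task | signal fraction (U) | s_P | 0.3 | - |
| task | signal intervals (U) | s_I | 20 | count |
| body | drag | f | 0.9 | 1/time |
| body | max exertion | delta | 2 | speed/time |
| body | max angular velocity | eps | pi/6 | rad/time |
| body | sensor gain | gamma | 3 | - |
| body | sensor offset | o | 2 | arena units |
| body | detection radius | d | 29 | arena units |
| body | interaction radius | lambda | 2 | arena units |
| body | perceptual threshold | phi | 0.01 | speed |
| net  | time constant | tau | [0.5, 16] | time units |
| net  | bias | theta | [-16, 16] | - |
| net  | synaptic weight | a | [-16, 16] | - |
| net  | sensor weight | b | [-20, 20] | - |
| GA   | population | - | 400 | genomes |
| GA   | generations | - | 1000 | - |
| GA   | mutation bound | - | 0.12 | gene units |
| GA   | elitism | - | 0.02 | fraction |
| GA   | crossover | - | 0.01 | fraction |

## Resolved ambiguities and numerical choices

**Drag form.**  The motor equation is implemented as
dv/dt = -v f + (o1+o2) delta, whose equilibrium matches the stated top
speed 2 delta / f (~4.44).  The variant dv/dt = -v (1-f) + ... (top
speed 40, implausible against d = 29) is available via
`BodyParams.printed_drag_form` for comparison runs.

**Sensor geometry.**  Sensor readings are computed from explicit sensor
coordinates (center +- o/2 perpendicular to the heading) and true
toroidal Euclidean distance, rather than from a law-of-cosines
expression; the coordinate construction is the geometrically correct
form and preserves left/right contrast at all distances.  Raw values
below zero (target beyond d) clamp to zero: no anti-signal.

**Time-constant map.**  Genes map linearly to parameters
(theta = 16 g, a = 16 g, b = 20 g).  Time constants must be positive,
so the tau gene maps through its magnitude: tau = 0.5 + 15.5 |g|,
giving [0.5, 16] — the lower end keeps tau >= 10 dt for Euler
stability.

**Bearing battery.**  24 bearings at pi/24 spacing from direct left
(-pi/2, inclusive) toward direct right (+pi/2, exclusive); a closed
interval would give 25 trials.  Bearings are measured with left
negative, matching the task convention; internally the target is placed
along heading - bearing.

**Signal schedules.**  Unreliable schedules are resolved per Euler step:
each of the s_I = 20 equal intervals (600 steps) contains one
contiguous on-block of round(s_P * 600) = 180 steps at a uniformly
random admissible offset, so the on-fraction is exactly 0.3.  Blocks in
adjacent intervals may (rarely) abut, merging two maximal runs; the
per-interval structure is the invariant.

**Fitness edge cases.**  The middle branch is not clamped below zero (a
forager that ends farther away than it started, but inside d, scores
negative).  A trial ending inside lambda without ever stopping is
scored by the printed rule on r_n alone (attack branch).  A tie at
exactly r_n = lambda takes the attack branch unless the trial is
explicitly marked not-attacked.  Zero path length in the attack branch
cannot occur under the attack rule (r0 >= 23); if forced, the function
warns and returns the middle branch.

**GA details.**  Rank selection: mutated offspring draw their parent
uniformly from the elite set (top 2%), not fitness-weighted from the
whole population.  Crossover children take the first 22 genes from one
elite and the last 23 from another, distinct, elite; they are not
additionally mutated.  If the elite set has a single member (small
scaled populations), crossover is skipped and those slots become
mutants.  Every genome is re-evaluated with fresh trial randomness each
generation (no common random numbers), so measured best fitness is not
monotone even though the elite lineage is preserved.

**Equilibria.**  Fixed points are found by multistart hybrid-Powell
root finding on the unscaled field -x + W sigma(x) + drive (tau does
not move the roots), with starts at the preimages of a motor-output
lattice ({0.05 ... 0.95} on the motor neurons, saturation corners for
the rest) plus random draws from the box that provably contains every
fixed point.  Solutions are kept below residual 1e-8 and deduplicated
within 1e-4.  Stability is read from the tau-scaled Jacobian
eigenvalues; "saddle" requires real parts of both signs, so the middle
point of a bistable single neuron is labelled "unstable" (a 1-D
repeller), not "saddle".

**Periodicity.**  An embodied agent is a periodic sampler if, with no
signal ever delivered, velocity recurrently dips to <= phi and the
trailing inter-dip intervals (at least 5, up to the last 10) have a
coefficient of variation under 5%.  The label must be unanimous over 10
random initial neural states; disagreement yields "irregular", which is
excluded from the periodic/non-periodic census.

**Perturbation protocols.**  Both protocols compare a perturbed run
(one signal block of the evolved length s_P T / s_I = 9 time units)
against a null run from the identical initial state; attack termination
is disabled so both traces cover the full horizon.  Movement-dependent
gating still applies during the block — a D forager moving fast
receives nothing even while the target signals.  Non-periodic foragers:
block onset after a 50-time-unit settling window; the response window
ends when both motor-neuron states have returned to within 0.01 of
their pre-onset values (censored at trial end if they never do);
deceleration relative to the null is listening, acceleration chasing.
Periodic foragers: block onset at the first sample (v <= phi) after the
transient; deltas in sample time, onset-to-next-sample period, and
distance over that period.  The published definition (chasing = shorter
sample + shorter period + less distance) does not say how mixed-sign
triples are labelled; records use a majority vote over the three
deltas, with the distance delta breaking ties.  The default grid is
target distances {5, 9, 13, 17, 21, 25} x the 24 battery bearings
(spanning just above the interaction radius to the trained band).  A
forager is a pure listener/chaser when >= 95% of non-null records share
one sign, "mixed" otherwise, "insensitive" if every record is null.

**Robustness lattice.**  5400 initial target positions on concentric
rings 0.5 apart between r = 2 and d = 29, per-ring counts proportional
to circumference, normalized separately inside and outside the trained
annulus [23, 27] so exactly 900 points land inside it; each position is
scored as mean fitness over 5 initial headings at 2 pi / 5 spacing.

**Numerics.**  The sigmoid is evaluated branch-stably (exact 0/1 at
extremes, no overflow).  The production integrator is a compiled
(numba) kernel; a pure-Python reference loop assembled from the public
ops is retained and the two agree to ~1e-14 per 600 steps (the residual
difference is BLAS summation order in the reference path).  Divergent
dynamics (NaN) abort a trial with fitness 0 and a flag.

## What the synthetic fixtures do and do not show

The hand-built genomes (`examples.py`) are constructive controls: a
cruiser (zero weights, motor biases -1) and a periodic sampler (a
two-neuron oscillator gating both motors through a high threshold,
period ~58 time units).  They verify that the classifiers respond to
the intended dynamical signatures, and — having no sensor weights —
that signal-insensitive agents are labelled as such.  They do not stand
in for evolved foragers: evolved strategies couple sensing to movement
in ways the fixtures deliberately lack, so fixture-level passes say
nothing about which strategies evolution actually discovers.  That
question is answered only by running the evolution pipeline.

## Problem sizes used by the test suite

Full-scale evolution (100 runs x 4 conditions x population 400 x 1000
generations) is a cluster-scale experiment.  The package's own test
battery instead runs: all closed-form and oracle checks at full trial
resolution; perturbation and classification protocols on fixture agents
at the full T = 600 horizon; and evolution scaled to population 60 for
100 generations under the RI condition, where a successful forager
(mean F > 1 on a fresh battery) with cruise-like no-signal behavior is
expected within a handful of seeds.  Scaled runs are regression
baselines, not reproductions of the full-scale strategy census; the
census structure (periodic samplers only under movement-dependent
perception, RI cruisers, and listening/chasing/mixed proportions) is
reachable through the CLI at full scale.

## Known limitations

- Fitness landscapes are evaluated with fresh randomness per
  generation; small populations can lose good genomes to evaluation
  noise despite elitism.
- The limit-cycle detector assumes cycles expressed in the motor
  outputs; purely hidden-unit oscillations with saturated motors are
  reported as no cycle (they produce no behavioral periodicity).
- "Irregular" intrinsic dynamics (neither a fixed point nor a regular
  cycle) are flagged and excluded rather than forced into the two-way
  periodicity census.
- The robustness map and perturbation grids are embarrassingly
  parallel but run serially.
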