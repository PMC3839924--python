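# Methods

This note documents the model, the synchronization cost, the three
estimators and every numerical choice behind the shipped defaults. It is
the place to look when a default looks arbitrary: each one is either a
structural property of the model or a value fixed once from exploratory
simulation of the reference system.

## Model

The network is two identical "modified repressilators" coupled by quorum
sensing. Per cell *i*: mRNA levels a (tetR), b (cI), c (lacI); protein
levels A (TetR), B (CI), C (LacI); intracellular autoinducer S. The
repression ring is C ⊣ a, A ⊣ b, B ⊣ c, each with the Hill term
α/(1 + p^n). The lacI equation carries the additional AI activation term
κ·S/(1 + S). Proteins relax toward their mRNA at rate β (a single
lifetime-ratio shared by all three proteins — the per-protein ratios are
deliberately not exposed). The AI is produced proportionally to CI
(rate k_s1), degrades (rate k_s0) and diffuses through the membrane
(coefficient η) against the extracellular level. The extracellular AI is
fast and is eliminated by a quasi-steady state, leaving the mean-field
S_e = Q·(S₁+S₂)/2 where the single parameter Q ∈ [0, 1] summarizes cell
density, external volume, external degradation and membrane permeability;
its microscopic constituents are out of scope. Because the AI feedback
competes with the ring's negative feedback, the cell-to-cell coupling is
phase-repulsive, which is what makes chaos possible in a two-cell
population.

State ordering is fixed everywhere as
`(a1, b1, c1, A1, B1, C1, S1, a2, b2, c2, A2, B2, C2, S2)`; coupling
indices refer to it.

**Reference chaotic parameter set.** α = 216, κ = 20, n = 2.6, β = 0.85,
k_s0 = 1, k_s1 = 0.01, η = 2, Q = 0.35. The first seven values are the
standard operating point for this model family; Q was placed by a
bifurcation/Lyapunov scan over Q ∈ [0, 1] at that operating point: the
oscillation amplitude maxima form broad bands (no low-period structure)
for Q ≈ 0.32–0.40, with a largest Lyapunov exponent ≈ 0.02 1/t.u. at
Q = 0.35, while Q ≳ 0.6 gives oscillation death and small Q gives periodic
or weakly chaotic regimes. The scan is reproducible via
`repsync bifurcate` or `bifurcation_scan`.

**Negative concentrations.** States are validated at initialization only.
Transient negative excursions during integration are not clipped (clipping
would alter the dynamics); a negative protein level raised to the
fractional Hill exponent produces NaN, the trajectory is flagged diverged,
and any cost built on it is +∞, which every estimator treats as a
rejection. This keeps the estimators well-defined without distorting the
vector field.

**Initial conditions.** The network is symmetric under cell exchange, so a
symmetric initial state stays on the synchronous manifold forever; the
default initial condition is deliberately asymmetric. Random draws use a
box of [0, 50] for mRNA/protein components and [0, 5] for the AI.

## Integration

Fixed-step explicit second-order Runge–Kutta; the default variant is
Heun's method (full Euler predictor, trapezoidal corrector), with explicit
midpoint available as a config switch. Default step dt = 0.01 t.u. —
roughly 2,500 steps per oscillation period, where the RK2 discretization
error is far below every tolerance used by the estimators. The empirical
convergence order on x′ = −x is 2.00 ± 0.02 over dt ∈ {0.04, 0.02, 0.01}.
A compiled (numba) kernel is used on the hot paths (bifurcation scans and
the synchronization cost, ~1–2 ms per cost evaluation); a generic Python
integrator with identical stepping serves as an independent slow path in
the tests. Bifurcation scans discard a 100 t.u. transient by default and
collect strict local maxima (plateaus excluded) of one state channel.

## Observations and the synchronization cost

The primary system is integrated from a (seeded) random initial state, a
100 t.u. transient is discarded, and the observed channels are sampled
every `sample_step` over the cost window. Default observed channels are
(a₁, a₂) — the first variable of each cell; any pair with one channel per
cell works, and single-channel coupling demonstrably does not synchronize
(the package ships that diagnostic).

The secondary system adds D·(u_k(t) − y_k(t)) to the two matching
equations only. Between observation samples the drive is linearly
interpolated onto the integration grid. The distance is the *average* over
the K sampled times of the summed squared channel errors (averaging, not
summing, keeps tolerances comparable across window lengths). An
8-channel extended variant accumulates the error over the full state of
cell 1 plus a₂, while coupling still acts through two equations.

Defaults, fixed once from exploratory runs of the reference system:

* **D = 5** (1/t.u.). The identical-parameter secondary locks within
  ≈ 40 t.u. for every D ≳ 3; D = 5 is comfortably above the threshold
  while keeping the coupling soft enough that observation noise is not
  amplified (see noise floor below). `find_coupling_threshold` scans D
  empirically.
* **Cost transient 50 t.u., window T = 50 t.u., sample_step 0.05 t.u.**
  (K = 1000). After 50 t.u. the distance at the truth is limited only by
  the drive-interpolation floor (~10⁻⁶–10⁻⁷), five orders below the
  mismatch signal of a 1% parameter error.
* The secondary initial condition is drawn once per estimator run and held
  fixed, so cost differences reflect parameters only; the post-transient
  distance is insensitive to it.

**Noise.** Observation noise is i.i.d. Gaussian per sample and channel.
With matched parameters the two-channel distance approaches 2σ² (each
channel contributes ≈ σ²); at D = 5 the measured value is 0.87–0.95 of
2σ² for σ ∈ {0.05, 0.1} — slightly below because the secondary partially
tracks the noise through the coupling. ABC tolerances at or below 2σ² are
therefore unreachable on noisy data, and the SMC config warns when a
schedule crosses that floor.

## Estimated parameters and priors

The shipped estimation subset is (Q, n, β, η) with independent uniform
priors / search boxes Q ∈ (0, 1), n ∈ (1, 4), β ∈ (0.1, 2), η ∈ (0.5, 4)
— wide, order-one boxes around the reference values. Any subset of the
eight parameters can be configured; α and κ work too but need their own
boxes. A relevant landscape feature: Q and η partially compensate (both
scale the AI exchange term), producing a shallow valley in the distance —
the minimum over η at Q 10% off the truth is ≈ 5·10⁻³, at 20% off
≈ 2·10⁻². Distinguishing along that valley requires tolerances below
~10⁻², which drives several defaults below.

## Accelerated random search

One coordinate is perturbed at a time with a zero-mean Gaussian whose
*search variance* starts at σ²_max, divides by the contraction factor on
every failure, and resets to σ²_max on strict improvement or on hitting
σ²_min. Candidates outside the box are redrawn (up to 100 times, then
clipped). The variance bookkeeping is per-parameter; a success resets only
the active parameter's variance. Defaults: σ²_max = ((hi−lo)/2)²,
σ²_min = (10⁻⁴(hi−lo))², contraction 2, M = 5 consecutive iterations per
parameter, 100 sweeps — a 2,000-evaluation budget under which all four
NQEs on clean data fall from O(10⁻¹) to 10⁻⁵–10⁻¹¹. Larger budgets only
help; the search is embarrassingly robust on this cost.

## ABC MCMC

A likelihood-free Metropolis random walk: proposals perturb every
parameter independently (Gaussian, fixed std); a proposal outside the
prior box repeats the current state *without* integrating (the prior
density is zero — no simulation is needed, and the complexity report
counts only simulated proposals); a simulated proposal over the tolerance
repeats the state; anything else is accepted, since the uniform-prior,
symmetric-proposal Metropolis ratio is 1. Defaults: ε = 0.3 (large enough
that a feasible start is found from prior draws within a few hundred
attempts), proposal std 6% of each prior span (small proposals mix too
slowly along the Q–η valley and bias the chain mean), chain length 2,000,
thinning factor 50 for histograms. At this tolerance the chain explores
the whole Q–η valley, so Q (and to a lesser degree η) retains errors of
order 10⁻²–10⁻¹ — the characteristic weakness of the MCMC variant at a
matched budget, one to three orders of magnitude worse than ARS.

## ABC SMC

Population 1 is rejection-sampled from the prior at ε₁; later populations
resample a previous particle by weight, perturb it with a fixed Gaussian
kernel, reject candidates outside the box (before simulating) or over the
tolerance, and weight survivors by π(θ)/Σⱼ wⱼ K(θ|θⱼ), normalized per
population. Defaults: schedule (0.5, 0.23, 0.105, 0.048, 0.022, 0.01) —
six populations, geometric ratio ≈ 0.46 — with B = 100 particles and
kernel std 4% of each prior span.

The schedule endpoints matter. ε₁ = 0.5 (≈ 1.5% prior acceptance) starts
from an already-localized population; a larger ε₁ is cheaper for
population 1 but leaves particles scattered over weakly-synchronized
plateaus of the landscape, from which tolerance drops of more than a
factor ≈ 3 are nearly impassable. ε_T = 0.01 pinches the Q–η valley
enough that the final weighted means reach NQE ≲ 10⁻⁴ on clean data.
The kernel width trades acceptance against importance-weight variance:
narrow kernels (≲ 2% of span) make the weight denominator collapse for
particles at the cloud's edge, producing spurious weighted-IQR spikes
across populations; 4% keeps the per-parameter weighted IQR essentially
monotone while the last population still accepts at a few percent. Total
cost is ~10–20 thousand secondary integrations, dominated by the final
population — the cost profile grows with the population index.

Posterior summaries use weighted means, weighted histograms over fixed
30-bin grids spanning the prior range (deterministic, comparable across
runs), and weighted box statistics (median, quartiles, 1.5·IQR whiskers).

## Method comparison

The comparison runs all three estimators on the same fixture and counts
secondary integrations. The shipped matched budget is 1,000 simulations
per method: large enough that ARS has entered its convergent phase, small
enough that the ordering is informative. Expected picture on clean data:
ARS and SMC recover all four parameters; MCMC's worst parameter (Q) is
one to three orders of magnitude worse in NQE.

## Reproducibility

All randomness flows through `numpy.random.default_rng` seeded from the
run seed (observation draw, ARS proposals, MCMC proposals, SMC
resampling/kernel, noise use separate seeded generators); identical seeds
give bit-identical traces, chains and populations. Every CLI output is a
CSV or JSON table regenerable from (config, seed); plots are optional
artifacts behind `--plot`.

## What the synthetic study does and does not show

All tests and shipped experiments use data generated by the package's own
primary-system simulator, so they validate the estimation machinery under
the model's own assumptions: identical functional form of primary and
secondary systems, two noiseless (or Gaussian-noise) observed channels on
a regular grid, stationary parameters. They do not probe model mismatch
(real mRNA/protein kinetics differing from Hill-type terms), non-Gaussian
or state-dependent measurement noise, irregular sampling, or networks of
more than two cells — all outside the package's scope. The noise study
shows the distance saturating at the 2σ² floor, so on noisy data
tolerances and achievable NQEs degrade accordingly.

## Known limitations

* The synchronization threshold D_c is located empirically, not derived;
  pathological channel choices (both channels from one cell) never
  synchronize and are reported as such.
* The Q–η compensation valley slows every estimator; at tolerances above
  ~10⁻² the valley, not the sampler, limits accuracy of Q and η.
* Fixed (non-adaptive) SMC kernels and schedules are a design choice for
  reproducibility; adaptive variants would reduce the cost of the last
  population but are out of scope.
* The fixed-step integrator is adequate for this non-stiff system at
  dt = 0.01; no stiff or adaptive integration is provided.
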