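# repsync

Synchronization-based parameter estimation for a chaotic intercellular
gene network: two modified repressilators coupled by quorum sensing.

## The problem

Models of coupled gene circuits are sets of nonlinear ODEs whose kinetic
parameters are rarely known. When the dynamics is chaotic, classical
trajectory-fitting is nearly hopeless: exponential sensitivity to initial
conditions makes the least-squares landscape wildly multimodal, and the
initial conditions themselves would have to be estimated too.

`repsync` implements an alternative built on *chaos synchronization*. The
data-generating network (the **primary** system) is a two-cell modified
repressilator: per cell, the three-gene ring tetR ⊣ cI ⊣ lacI ⊣ tetR plus a
quorum-sensing feedback in which the autoinducer (AI) molecule diffuses
through the membrane and activates a second *lacI* copy. In dimensionless
form, for cell *i* ∈ {1, 2}:

    da_i/dt = −a_i + α/(1 + C_i^n)
    db_i/dt = −b_i + α/(1 + A_i^n)
    dc_i/dt = −c_i + α/(1 + B_i^n) + κ S_i/(1 + S_i)
    dA_i/dt = β (a_i − A_i)        (and likewise B_i, C_i)
    dS_i/dt = −k_s0 S_i + k_s1 B_i − η (S_i − S_e)

with the extracellular AI eliminated by a quasi-steady-state approximation,
S_e = Q (S_1 + S_2)/2, Q ∈ [0, 1]. The shipped reference set
(α = 216, κ = 20, n = 2.6, β = 0.85, k_s0 = 1, k_s1 = 0.01, η = 2,
Q = 0.35) lies in a chaotic window of the bifurcation diagrams.

Only two scalar channels are observed: the first variable (tetR mRNA) of
each cell, u(t) = (a_1(t), a_2(t)). A **secondary** system — a model copy
with adjustable parameters θ̂ — is driven diffusively by these data,
adding D·(u_k(t) − y_k(t)) to the two matching equations. When θ̂ equals
the true θ\* and D exceeds the synchronization threshold, the secondary
locks onto the primary and the cost

    J(θ̂) = (1/K) Σ_k Σ_{c∈channels} (u_c(t_k) − y_c(t_k))²

drops to numerical zero; any parameter mismatch leaves a residual error.
Initial conditions never need to be estimated — the drive erases them.

Three likelihood-free estimators minimize or threshold J:

* **ARS** (accelerated random search): coordinate-wise Gaussian search
  whose variance contracts on failure and resets on success;
* **ABC MCMC**: a Metropolis random walk restricted to {θ : J(θ) ≤ ε};
* **ABC SMC**: weighted particle populations pushed through a decreasing
  tolerance schedule ε_1 > … > ε_T.

Accuracy is reported as the normalized quadratic error per parameter,
NQE_l = ((θ̂_l − θ\*_l)/θ\*_l)². Computational cost is counted in secondary
integrations (one per candidate parameter vector).

## Worked example

```python
import repsync

theta = repsync.reference_chaotic_params()      # ground truth
obs = repsync.simulate_observations(theta, seed=0)   # two observed channels

est = repsync.ABCSMCEstimator(seed=0).fit(obs)  # 6 populations, B=100
print({k: round(v, 4) for k, v in est.estimates_.items()})
print(repsync.nqe(est.theta_, theta, which=("Q", "n", "beta", "eta")))
print(est.complexity_["cumulative"])
```

Output from this exact snippet:

```
{'Q': 0.3484, 'n': 2.6081, 'beta': 0.8505, 'eta': 2.01}
{'Q': 2.1981735864348556e-05, 'n': 9.762932071971505e-06, 'beta': 3.8895694916432705e-07, 'eta': 2.4848898947527724e-05}
[4042, 4678, 5509, 6711, 9300, 14698]
```

The weighted means of the final population recover all four estimated
parameters (Q, n, β, η) to a fraction of a percent — NQE below 3·10⁻⁵ —
after 14,698 secondary integrations, with the cumulative cost growing as
the tolerance tightens. `ARSEstimator` and `ABCMCMCEstimator` expose the
same `fit`/`estimates_` interface; all three are scikit-learn compatible
(`get_params`/`set_params`/`clone`).

The same pipeline is scriptable from the shell:

```bash
repsync make-fixture --outdir out --seed 0
repsync estimate-ars --outdir out --seed 0
repsync bifurcate --control Q --lo 0 --hi 1 --num 101 --outdir out --plot
```

## Layout

| module | contents |
|---|---|
| `repsync.model` | ODE right-hand side, `ParameterSet`, reference chaotic values |
| `repsync.integrate` | fixed-step RK2 (Heun/midpoint), maxima detection, bifurcation scans |
| `repsync.sync` | driven secondary system, synchronization distance, noise model |
| `repsync.ars` | accelerated random search |
| `repsync.abc` | ABC rejection / MCMC / SMC, posterior summaries, complexity accounting |
| `repsync.estimators` | scikit-learn-style estimator classes |
| `repsync.cli` | `repsync` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
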