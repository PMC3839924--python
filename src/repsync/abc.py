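"""Likelihood-free (ABC) posterior approximation over the sync distance.

Three samplers share the same ingredients — a uniform prior box, a
distance function (the synchronization error of the driven secondary
system) and a tolerance epsilon:

* :func:`abc_rejection` — keep prior draws whose distance is within
  epsilon;
* :func:`abc_mcmc` — a Metropolis-Hastings random walk that only ever
  visits parameter values whose distance is within epsilon (with a uniform
  prior and a symmetric Gaussian proposal the Metropolis ratio is 1, so a
  proposal is accepted exactly when it stays in the box and meets the
  tolerance);
* :func:`abc_smc` — a sequential importance sampler that propagates a
  population of weighted particles through a strictly decreasing tolerance
  schedule, perturbing resampled particles with a Gaussian kernel and
  reweighting them per the standard SMC importance weight.

Every candidate that reaches the distance function costs one secondary
integration; all samplers count these draws, the complexity currency used
to compare the methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ars import DEFAULT_BOUNDS, ARSTrace
from .model import PARAM_NAMES, ParameterSet
from .sync import noise_floor, nqe

__all__ = [
    "PriorBox", "MCMCConfig", "SMCConfig", "Chain", "Population",
    "abc_rejection", "abc_mcmc", "abc_smc", "posterior_summary",
    "complexity_report", "smc_weights_bruteforce",
]

HISTOGRAM_BINS = 30


@dataclass(frozen=True)
class PriorBox:
    """Independent uniform priors, one (lo, hi) interval per parameter."""

    bounds: tuple = tuple(DEFAULT_BOUNDS.items())

    def __post_init__(self):
        if isinstance(self.bounds, dict):
            object.__setattr__(self, "bounds", tuple(self.bounds.items()))
        for k, (lo, hi) in self.bounds:
            if lo >= hi:
                raise ValueError(f"prior for {k}: need lo < hi")

    @property
    def names(self) -> tuple:
        return tuple(k for k, _ in self.bounds)

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for _, b in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for _, b in self.bounds])

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    def sample(self, rng, size=None) -> np.ndarray:
        if size is None:
            return rng.uniform(self.lo, self.hi)
        return rng.uniform(self.lo, self.hi, size=(size, len(self.bounds)))

    def contains(self, theta) -> bool:
        theta = np.asarray(theta)
        return bool(np.all(theta >= self.lo) and np.all(theta <= self.hi))

    def pdf(self, theta) -> float:
        return 1.0 / self.volume if self.contains(theta) else 0.0


@dataclass
class MCMCConfig:
    """ABC MCMC settings.

    epsilon : synchronization-error tolerance every chain state satisfies.
    proposal_sigma : per-parameter std of the Gaussian random-walk proposal
        (scalar, dict or None; default 6% of each prior span).
    chain_length : number of MCMC steps (proposals considered).
    subsample : thinning factor applied when summarizing the chain.
    """

    epsilon: float = 0.3
    proposal_sigma: object = None
    chain_length: int = 2000
    subsample: int = 50
    seed: int = None

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.subsample < 1:
            raise ValueError("subsample must be >= 1")
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")

    def sigmas(self, prior: PriorBox) -> np.ndarray:
        if self.proposal_sigma is None:
            return 0.06 * (prior.hi - prior.lo)
        if np.isscalar(self.proposal_sigma):
            return np.full(len(prior.names), float(self.proposal_sigma))
        return np.array([float(self.proposal_sigma[k]) for k in prior.names])


@dataclass
class SMCConfig:
    """ABC SMC settings.

    epsilons : strictly decreasing tolerance schedule.
    n_particles : particles (B) kept per population.
    kernel_sigma : per-parameter std of the Gaussian perturbation kernel
        (scalar, dict or None; default 4% of each prior span).
    max_draws_per_population : abort guard against infeasible tolerances.
    """

    epsilons: tuple = (0.5, 0.23, 0.105, 0.048, 0.022, 0.01)
    n_particles: int = 100
    kernel_sigma: object = None
    max_draws_per_population: int = 500_000
    seed: int = None

    def __post_init__(self):
        self.epsilons = tuple(float(e) for e in self.epsilons)
        if any(e <= 0 for e in self.epsilons):
            raise ValueError("tolerances must be positive")
        if any(a <= b for a, b in zip(self.epsilons, self.epsilons[1:])):
            raise ValueError("tolerance schedule must be strictly decreasing")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")

    def sigmas(self, prior: PriorBox) -> np.ndarray:
        if self.kernel_sigma is None:
            return 0.04 * (prior.hi - prior.lo)
        if np.isscalar(self.kernel_sigma):
            return np.full(len(prior.names), float(self.kernel_sigma))
        return np.array([float(self.kernel_sigma[k]) for k in prior.names])

    def check_noise_feasibility(self, noise_sigma: float) -> list[str]:
        """Warn-level check: tolerances at or below the noise floor
        2*sigma**2 are unreachable on noisy observations."""
        floor = noise_floor(noise_sigma)
        return [f"epsilon={e} is <= noise floor {floor}"
                for e in self.epsilons if e <= floor]


@dataclass
class Chain:
    """Output of :func:`abc_mcmc`.

    ``samples[0]`` is the initial state; ``flags`` per step:
    ``accept`` (moved), ``repeat`` (simulated, over tolerance) or
    ``prior_reject`` (left the box; repeated without simulating).
    """

    param_names: tuple
    samples: np.ndarray
    distances: np.ndarray
    flags: np.ndarray
    epsilon: float

    @property
    def n_simulated(self) -> int:
        """Secondary-system integrations spent (excludes prior rejections
        and the initial state)."""
        return int(np.sum(self.flags != "prior_reject")) - 1

    def thinned(self, subsample: int) -> np.ndarray:
        return self.samples[::subsample]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.param_names))
        df["distance"] = self.distances
        df["flag"] = self.flags
        return df


@dataclass
class Population:
    """One weighted particle set of the SMC sequence."""

    param_names: tuple
    particles: np.ndarray
    weights: np.ndarray
    distances: np.ndarray
    epsilon: float
    draws_used: int

    def __post_init__(self):
        s = self.weights.sum()
        if not np.isclose(s, 1.0, rtol=1e-9):
            raise ValueError("weights must be normalized")
        if np.any(self.distances > self.epsilon):
            raise ValueError("stored particle exceeds the tolerance")

    def weighted_mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def to_dataframe(self, index=None) -> pd.DataFrame:
        df = pd.DataFrame(self.particles, columns=list(self.param_names))
        df["weight"] = self.weights
        df["distance"] = self.distances
        if index is not None:
            df["population"] = index
        return df


def abc_rejection(prior: PriorBox, dist, epsilon: float, n_accept: int,
                  seed=None, max_attempts: int = None):
    """Plain ABC rejection sampler.

    Draws from the prior and keeps values with ``dist(theta) <= epsilon``
    until ``n_accept`` are kept.  Returns ``(samples, attempts, complete)``;
    hitting ``max_attempts`` returns the partial result with
    ``complete=False``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rng = np.random.default_rng(seed)
    kept = []
    attempts = 0
    while len(kept) < n_accept:
        if max_attempts is not None and attempts >= max_attempts:
            return np.array(kept).reshape(len(kept), len(prior.names)), attempts, False
        theta = prior.sample(rng)
        attempts += 1
        if dist(theta) <= epsilon:
            kept.append(theta)
    return np.array(kept), attempts, True


def abc_mcmc(prior: PriorBox, dist, cfg: MCMCConfig, theta_init) -> Chain:
    """Likelihood-free Metropolis-Hastings chain under tolerance epsilon.

    The initial state must already meet the tolerance.  Each step perturbs
    every parameter with an independent Gaussian; proposals outside the
    prior box repeat the current state without simulating, proposals over
    the tolerance repeat it after simulating, and the rest are accepted
    (the Metropolis ratio is 1 for a uniform prior and symmetric proposal).
    """
    rng = np.random.default_rng(cfg.seed)
    theta = np.asarray(theta_init, dtype=float)
    d0 = float(dist(theta))
    if not d0 <= cfg.epsilon:
        raise ValueError(
            f"initial state has distance {d0} > epsilon {cfg.epsilon}")
    sig = cfg.sigmas(prior)
    p = len(prior.names)
    n = cfg.chain_length
    samples = np.empty((n + 1, p))
    distances = np.empty(n + 1)
    flags = np.empty(n + 1, dtype=object)
    samples[0] = theta
    distances[0] = d0
    flags[0] = "init"
    d_cur = d0
    for k in range(1, n + 1):
        cand = samples[k - 1] + rng.normal(0.0, sig, size=p)
        if not prior.contains(cand):
            samples[k] = samples[k - 1]
            distances[k] = d_cur
            flags[k] = "prior_reject"
            continue
        d = float(dist(cand))
        if np.isnan(d):
            d = np.inf
        if d <= cfg.epsilon:
            samples[k] = cand
            distances[k] = d
            flags[k] = "accept"
            d_cur = d
        else:
            samples[k] = samples[k - 1]
            distances[k] = d_cur
            flags[k] = "repeat"
    return Chain(param_names=prior.names, samples=samples,
                 distances=distances, flags=flags, epsilon=cfg.epsilon)


def _kernel_matrix(cands, prev, sig):
    """K[i, j] = Gaussian kernel density of candidate i centred at previous
    particle j (product over parameters)."""
    diff = cands[:, None, :] - prev[None, :, :]
    z = diff / sig
    log_k = -0.5 * np.sum(z ** 2, axis=2) \
        - np.sum(np.log(sig * np.sqrt(2 * np.pi)))
    return np.exp(log_k)


def smc_weights_bruteforce(prior: PriorBox, cands, prev, prev_w, sig):
    """Unnormalized SMC weights by an explicit double loop (oracle form)."""
    out = np.empty(len(cands))
    for i, th in enumerate(cands):
        denom = 0.0
        for j, pj in enumerate(prev):
            k = 1.0
            for l in range(len(sig)):
                z = (th[l] - pj[l]) / sig[l]
                k *= np.exp(-0.5 * z * z) / (sig[l] * np.sqrt(2 * np.pi))
            denom += prev_w[j] * k
        out[i] = prior.pdf(th) / denom
    return out


def abc_smc(prior: PriorBox, dist, cfg: SMCConfig) -> list[Population]:
    """Sequential ABC: populations of weighted particles under a strictly
    decreasing tolerance schedule.

    Population 1 is sampled from the prior subject to the first tolerance,
    with uniform weights.  Later populations resample a previous particle
    proportionally to its weight, perturb it with the Gaussian kernel,
    reject candidates outside the prior box (no simulation) or over the
    tolerance, and weight accepted particles by
    ``prior(theta) / sum_j w_j * K(theta | theta_j)``, normalizing at the
    end.  ``draws_used`` counts the simulated candidates per population.
    """
    rng = np.random.default_rng(cfg.seed)
    sig = cfg.sigmas(prior)
    p = len(prior.names)
    B = cfg.n_particles
    populations: list[Population] = []
    prev = prev_w = None
    for t, eps in enumerate(cfg.epsilons):
        parts = np.empty((B, p))
        dists = np.empty(B)
        raw_w = np.empty(B)
        draws = 0
        i = 0
        while i < B:
            if draws >= cfg.max_draws_per_population:
                raise RuntimeError(
                    f"population {t + 1} (eps={eps}): exceeded "
                    f"{cfg.max_draws_per_population} draws with {i} accepted")
            if t == 0:
                cand = prior.sample(rng)
            else:
                j = rng.choice(B, p=prev_w)
                cand = prev[j] + rng.normal(0.0, sig, size=p)
                if not prior.contains(cand):
                    continue
            d = float(dist(cand))
            if np.isnan(d):
                d = np.inf
            draws += 1
            if d > eps:
                continue
            parts[i] = cand
            dists[i] = d
            if t == 0:
                raw_w[i] = 1.0
            else:
                denom = prev_w @ _kernel_matrix(cand[None, :], prev, sig)[0]
                raw_w[i] = prior.pdf(cand) / denom
            i += 1
        w = raw_w / raw_w.sum()
        populations.append(Population(
            param_names=prior.names, particles=parts, weights=w,
            distances=dists, epsilon=eps, draws_used=draws))
        prev, prev_w = parts, w
    return populations


def _weighted_quantile(values, weights, q):
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw = cw / cw[-1]
    return float(np.interp(q, cw, v))


def _box_stats(values, weights):
    """Median/quartile/whisker summary (1.5 IQR rule) with weights."""
    q1 = _weighted_quantile(values, weights, 0.25)
    med = _weighted_quantile(values, weights, 0.5)
    q3 = _weighted_quantile(values, weights, 0.75)
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = (values >= lo_lim) & (values <= hi_lim)
    return {
        "median": med, "q1": q1, "q3": q3, "iqr": iqr,
        "whisker_lo": float(values[inside].min()) if inside.any() else med,
        "whisker_hi": float(values[inside].max()) if inside.any() else med,
        "outliers": values[~inside].tolist(),
    }


def posterior_summary(result, theta_star: ParameterSet = None,
                      subsample: int = None, prior: PriorBox = None,
                      bins: int = HISTOGRAM_BINS) -> dict:
    """Weighted means, histograms, NQEs and box statistics.

    ``result`` may be a :class:`Chain` (thinned by ``subsample``, default
    the chain config's convention of 50), a :class:`Population`, a list of
    populations (summaries per population, means/NQE from the last) or a
    plain array of samples.  Histogram bins span the prior range when a
    prior is given (fixed equal-width binning), else the sample range.
    """
    per_population = None
    if isinstance(result, Chain):
        names = result.param_names
        samples = result.thinned(subsample or 50)
        weights = np.full(len(samples), 1.0 / len(samples))
    elif isinstance(result, Population):
        names = result.param_names
        samples, weights = result.particles, result.weights
    elif isinstance(result, (list, tuple)) and result \
            and isinstance(result[0], Population):
        names = result[-1].param_names
        samples, weights = result[-1].particles, result[-1].weights
        per_population = [
            {k: _box_stats(pop.particles[:, j], pop.weights)
             for j, k in enumerate(pop.param_names)}
            for pop in result]
    else:
        samples = np.asarray(result, dtype=float)
        if samples.ndim != 2:
            raise ValueError("expected a 2-D sample array")
        names = prior.names if prior is not None \
            else tuple(f"p{j}" for j in range(samples.shape[1]))
        weights = np.full(len(samples), 1.0 / len(samples))
    if len(samples) == 0:
        raise ValueError("no samples to summarize")
    means = {k: float(weights @ samples[:, j]) for j, k in enumerate(names)}
    hists = {}
    for j, k in enumerate(names):
        if prior is not None:
            rng_j = dict(prior.bounds)[k]
        else:
            rng_j = (samples[:, j].min(), samples[:, j].max())
        counts, edges = np.histogram(samples[:, j], bins=bins, range=rng_j,
                                     weights=weights)
        hists[k] = (counts, edges)
    out = {"mean": means, "histograms": hists,
           "box": {k: _box_stats(samples[:, j], weights)
                   for j, k in enumerate(names)}}
    if per_population is not None:
        out["box_per_population"] = per_population
    if theta_star is not None:
        theta_hat = theta_star.replace(**means)
        out["nqe"] = nqe(theta_hat, theta_star, which=names)
    return out


def complexity_report(result) -> dict:
    """Cumulative number of random samples generated (one secondary
    integration each): total for ARS/MCMC, per-population cumulative for
    SMC."""
    if isinstance(result, ARSTrace):
        return {"method": "ars", "total": int(result.n_evaluations)}
    if isinstance(result, Chain):
        return {"method": "abc_mcmc", "total": int(result.n_simulated) + 1}
    if isinstance(result, (list, tuple)) and result \
            and isinstance(result[0], Population):
        cum = np.cumsum([p.draws_used for p in result]).tolist()
        return {"method": "abc_smc", "cumulative": cum, "total": cum[-1]}
    raise TypeError("unsupported result type")
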