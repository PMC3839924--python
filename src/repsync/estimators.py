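"""Scikit-learn-style estimator interfaces over the three samplers.

Each estimator wraps one inference scheme behind the familiar
``fit`` / fitted-attribute contract so runs compose with sklearn tooling
(``get_params`` / ``set_params``, ``clone``, grid search over algorithm
settings).  ``fit`` takes an :class:`~repsync.sync.ObservationSet` — the
two observed scalar channels of the primary system — and recovers the
configured parameter subset by driving the secondary system.

Fitted attributes (trailing underscore):

* ``theta_`` — point estimate as a :class:`~repsync.model.ParameterSet`
  (ARS: best point; ABC: posterior/weighted mean);
* ``estimates_`` — the same as a name -> value dict over ``param_names``;
* ``n_simulations_`` — secondary-system integrations spent;
* method-specific artifacts: ``trace_`` (ARS), ``chain_`` (MCMC),
  ``populations_`` (SMC).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .abc import (MCMCConfig, PriorBox, SMCConfig, abc_mcmc, abc_smc,
                  complexity_report, posterior_summary)
from .ars import ARSConfig, DEFAULT_BOUNDS, ars_minimize
from .integrate import DEFAULT_DT
from .model import ParameterSet
from .sync import CostConfig, CouplingSpec, ObservationSet, SyncCost

__all__ = ["ARSEstimator", "ABCMCMCEstimator", "ABCSMCEstimator"]


class _SyncEstimatorBase(BaseEstimator):
    """Shared plumbing: build the synchronization cost from observations."""

    def _validate_obs(self, X) -> ObservationSet:
        if not isinstance(X, ObservationSet):
            raise TypeError("X must be an ObservationSet "
                            "(see repsync.simulate_observations)")
        if len(X.times) < 2:
            raise ValueError("observations must hold at least two samples")
        return X

    def _bounds(self) -> dict:
        if self.bounds is not None:
            return dict(self.bounds)
        return {k: DEFAULT_BOUNDS[k] for k in self.param_names}

    def _make_cost(self, obs: ObservationSet, seed) -> SyncCost:
        base = self.base_theta or ParameterSet()
        spec = self.coupling or CouplingSpec()
        cfg = self.cost or CostConfig()
        rng = np.random.default_rng(seed)
        from .sync import _draw_initial_state
        y0 = _draw_initial_state(rng)  # fixed within the run
        return SyncCost(obs, self.param_names, base_theta=base, spec=spec,
                        cfg=cfg, y0=y0, dt=self.dt)

    def _set_estimate(self, values):
        base = self.base_theta or ParameterSet()
        self.estimates_ = dict(zip(self.param_names,
                                   (float(v) for v in values)))
        self.theta_ = base.replace(**self.estimates_)

    def score(self, X, y=None) -> float:
        """Negative synchronization distance of the fitted estimate."""
        obs = self._validate_obs(X)
        cost = self._make_cost(obs, self.seed)
        return -cost([self.estimates_[k] for k in self.param_names])


class ARSEstimator(_SyncEstimatorBase):
    """Point estimation by accelerated random search.

    Parameters mirror :class:`~repsync.ars.ARSConfig`; ``coupling``,
    ``cost`` and ``dt`` control the driven secondary system.
    """

    def __init__(self, param_names=("Q", "n", "beta", "eta"), bounds=None,
                 sigma_max=None, sigma_min=None, contraction=2.0,
                 iters_per_param=5, n_sweeps=100, cost_threshold=0.0,
                 base_theta=None, coupling=None, cost=None, dt=DEFAULT_DT,
                 seed=None):
        self.param_names = tuple(param_names)
        self.bounds = bounds
        self.sigma_max = sigma_max
        self.sigma_min = sigma_min
        self.contraction = contraction
        self.iters_per_param = iters_per_param
        self.n_sweeps = n_sweeps
        self.cost_threshold = cost_threshold
        self.base_theta = base_theta
        self.coupling = coupling
        self.cost = cost
        self.dt = dt
        self.seed = seed

    def fit(self, X, y=None):
        obs = self._validate_obs(X)
        cost = self._make_cost(obs, self.seed)
        cfg = ARSConfig(param_names=self.param_names, bounds=self._bounds(),
                        sigma_max=self.sigma_max, sigma_min=self.sigma_min,
                        contraction=self.contraction,
                        iters_per_param=self.iters_per_param,
                        n_sweeps=self.n_sweeps,
                        cost_threshold=self.cost_threshold, seed=self.seed)
        self.trace_ = ars_minimize(cost, cfg)
        self.n_simulations_ = cost.n_calls
        self.best_cost_ = float(self.trace_.best_cost[-1])
        self._set_estimate(self.trace_.final_theta)
        return self


class ABCMCMCEstimator(_SyncEstimatorBase):
    """Posterior sampling by likelihood-free MCMC; the point estimate is
    the mean of the thinned chain.

    The chain is started from the best of repeated prior draws once one
    meets the tolerance (those draws count toward ``n_simulations_``).
    """

    def __init__(self, param_names=("Q", "n", "beta", "eta"), bounds=None,
                 epsilon=0.3, proposal_sigma=None, chain_length=2000,
                 subsample=50, max_init_draws=100_000, base_theta=None,
                 coupling=None, cost=None, dt=DEFAULT_DT, seed=None):
        self.param_names = tuple(param_names)
        self.bounds = bounds
        self.epsilon = epsilon
        self.proposal_sigma = proposal_sigma
        self.chain_length = chain_length
        self.subsample = subsample
        self.max_init_draws = max_init_draws
        self.base_theta = base_theta
        self.coupling = coupling
        self.cost = cost
        self.dt = dt
        self.seed = seed

    def fit(self, X, y=None):
        obs = self._validate_obs(X)
        cost = self._make_cost(obs, self.seed)
        prior = PriorBox(self._bounds())
        rng = np.random.default_rng(
            None if self.seed is None else self.seed + 1)
        init = None
        for _ in range(self.max_init_draws):
            cand = prior.sample(rng)
            if cost(cand) <= self.epsilon:
                init = cand
                break
        if init is None:
            raise RuntimeError(
                f"no initial state with distance <= {self.epsilon} found "
                f"in {self.max_init_draws} prior draws")
        self.n_init_draws_ = cost.n_calls
        cfg = MCMCConfig(epsilon=self.epsilon,
                         proposal_sigma=self.proposal_sigma,
                         chain_length=self.chain_length,
                         subsample=self.subsample, seed=self.seed)
        self.chain_ = abc_mcmc(prior, cost, cfg, init)
        self.n_simulations_ = cost.n_calls
        self.summary_ = posterior_summary(
            self.chain_, theta_star=None, subsample=self.subsample,
            prior=prior)
        self._set_estimate([self.summary_["mean"][k]
                            for k in self.param_names])
        return self


class ABCSMCEstimator(_SyncEstimatorBase):
    """Posterior sampling by sequential ABC; the point estimate is the
    weighted mean of the final population."""

    def __init__(self, param_names=("Q", "n", "beta", "eta"), bounds=None,
                 epsilons=(0.5, 0.23, 0.105, 0.048, 0.022, 0.01),
                 n_particles=100, kernel_sigma=None,
                 max_draws_per_population=500_000, base_theta=None,
                 coupling=None, cost=None, dt=DEFAULT_DT, seed=None):
        self.param_names = tuple(param_names)
        self.bounds = bounds
        self.epsilons = tuple(epsilons)
        self.n_particles = n_particles
        self.kernel_sigma = kernel_sigma
        self.max_draws_per_population = max_draws_per_population
        self.base_theta = base_theta
        self.coupling = coupling
        self.cost = cost
        self.dt = dt
        self.seed = seed

    def fit(self, X, y=None):
        obs = self._validate_obs(X)
        cost = self._make_cost(obs, self.seed)
        prior = PriorBox(self._bounds())
        cfg = SMCConfig(epsilons=self.epsilons, n_particles=self.n_particles,
                        kernel_sigma=self.kernel_sigma,
                        max_draws_per_population=self.max_draws_per_population,
                        seed=self.seed)
        warn = cfg.check_noise_feasibility(obs.noise_sigma)
        if warn:
            import warnings
            warnings.warn("; ".join(warn), stacklevel=2)
        self.populations_ = abc_smc(prior, cost, cfg)
        self.n_simulations_ = cost.n_calls
        self.summary_ = posterior_summary(self.populations_, prior=prior)
        self.complexity_ = complexity_report(self.populations_)
        self._set_estimate([self.summary_["mean"][k]
                            for k in self.param_names])
        return self
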