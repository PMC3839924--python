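"""Accelerated random search (ARS) over the synchronization distance.

ARS is a coordinate-wise stochastic optimizer.  It perturbs one parameter
at a time with a Gaussian proposal whose *search variance* contracts every
time the candidate fails to improve the best cost and resets to its maximum
on success (or when the minimum variance is reached).  The contraction
makes the search increasingly local around the incumbent, while the resets
let it escape again — an effective scheme on the rugged cost landscapes
produced by chaotic dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PARAM_NAMES, ParameterSet
from .sync import nqe

__all__ = ["ARSConfig", "ARSTrace", "ars_minimize", "ars_estimate_report",
           "DEFAULT_BOUNDS"]

#: Shipped search box for the four estimated parameters; also the
#: uniform-prior box of the ABC schemes and the ARS init-draw box.
DEFAULT_BOUNDS = {
    "Q": (0.0, 1.0),
    "n": (1.0, 4.0),
    "beta": (0.1, 2.0),
    "eta": (0.5, 4.0),
}

DEFAULT_PARAMS = tuple(DEFAULT_BOUNDS)


def _per_param(value, names, default_fn):
    """Normalize scalar / dict / None specs into a per-parameter array."""
    if value is None:
        return np.array([default_fn(k) for k in names], dtype=float)
    if np.isscalar(value):
        return np.full(len(names), float(value))
    return np.array([float(value[k]) for k in names], dtype=float)


@dataclass
class ARSConfig:
    """Configuration of the ARS loop.

    param_names : parameters of :class:`ParameterSet` to estimate.
    bounds : per-parameter (lo, hi) search box; also the init-draw box.
    sigma_max, sigma_min : maximum / minimum search *variances* per
        parameter (proposal std is the square root).  Defaults:
        ((hi-lo)/2)**2 and (1e-4*(hi-lo))**2.
    contraction : variance division factor on failure (> 1), default 2.
    iters_per_param : consecutive iterations per parameter (M).
    n_sweeps : outer sweeps over the parameter list; the total budget is
        n_sweeps * len(param_names) * iters_per_param cost evaluations.
    cost_threshold : stop early once the best cost falls at or below this.
    """

    param_names: tuple = DEFAULT_PARAMS
    bounds: dict = None
    sigma_max: object = None
    sigma_min: object = None
    contraction: object = 2.0
    iters_per_param: int = 5
    n_sweeps: int = 100
    cost_threshold: float = 0.0
    seed: int = None

    def __post_init__(self):
        self.param_names = tuple(self.param_names)
        unknown = set(self.param_names) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        if self.bounds is None:
            self.bounds = {k: DEFAULT_BOUNDS[k] for k in self.param_names}
        missing = set(self.param_names) - set(self.bounds)
        if missing:
            raise ValueError(f"bounds missing for: {sorted(missing)}")
        self.lo = np.array([self.bounds[k][0] for k in self.param_names])
        self.hi = np.array([self.bounds[k][1] for k in self.param_names])
        if np.any(self.lo >= self.hi):
            raise ValueError("bounds must satisfy lo < hi")
        span = self.hi - self.lo
        names = self.param_names
        self.sig_max = _per_param(
            self.sigma_max, names,
            lambda k: (0.5 * (self.bounds[k][1] - self.bounds[k][0])) ** 2)
        self.sig_min = _per_param(
            self.sigma_min, names,
            lambda k: (1e-4 * (self.bounds[k][1] - self.bounds[k][0])) ** 2)
        self.contr = _per_param(self.contraction, names, lambda k: 2.0)
        if np.any(self.sig_min <= 0) or np.any(self.sig_min >= self.sig_max):
            raise ValueError("need 0 < sigma_min < sigma_max per parameter")
        if np.any(self.contr <= 1):
            raise ValueError("contraction factors must exceed 1")
        if self.iters_per_param < 1:
            raise ValueError("iters_per_param must be >= 1")

    @property
    def total_iterations(self) -> int:
        return self.n_sweeps * len(self.param_names) * self.iters_per_param


@dataclass
class ARSTrace:
    """Iteration-by-iteration record of an ARS run.

    Row 0 of ``best_theta``/``best_cost`` is the initial draw; row k >= 1
    is the state after iteration k.  ``variances[k]`` holds the
    per-parameter search variances after iteration k's update resolved;
    ``accepted[k]`` flags an improvement at iteration k.
    """

    param_names: tuple
    best_theta: np.ndarray
    best_cost: np.ndarray
    variances: np.ndarray
    accepted: np.ndarray
    n_evaluations: int

    @property
    def final_theta(self) -> np.ndarray:
        return self.best_theta[-1]

    def final_parameter_set(self, base: ParameterSet = None) -> ParameterSet:
        base = base or ParameterSet()
        return base.replace(**dict(zip(self.param_names, self.final_theta)))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.best_theta, columns=list(self.param_names))
        df.insert(0, "iteration", np.arange(len(self.best_cost)))
        df["best_cost"] = self.best_cost
        for j, k in enumerate(self.param_names):
            df[f"variance_{k}"] = np.concatenate(
                [[np.nan], self.variances[:, j]])
        df["accepted"] = np.concatenate([[False], self.accepted])
        df.to_csv(path, index=False)


def ars_minimize(cost, cfg: ARSConfig) -> ARSTrace:
    """Minimize ``cost`` (a callable on parameter vectors) with ARS.

    The initial point is drawn uniformly in the bounds box and every search
    variance starts at its maximum.  The loop then cycles over the
    parameters; for the active parameter l it repeats ``iters_per_param``
    times: perturb only coordinate l with a zero-mean Gaussian of the
    current variance (redrawn up to 100 times if outside the box, then
    clipped), evaluate the cost, accept on strict improvement and reset
    variance l to its maximum, otherwise contract it, resetting to the
    maximum whenever it falls below the minimum.  NaN costs are treated as
    +inf (rejection).
    """
    rng = np.random.default_rng(cfg.seed)
    p = len(cfg.param_names)
    theta = rng.uniform(cfg.lo, cfg.hi)
    j0 = cost(theta)
    j0 = np.inf if np.isnan(j0) else float(j0)
    n_total = cfg.total_iterations
    best_theta = np.empty((n_total + 1, p))
    best_cost = np.empty(n_total + 1)
    variances = np.empty((n_total, p))
    accepted = np.zeros(n_total, dtype=bool)
    best_theta[0] = theta
    best_cost[0] = j0
    sig = cfg.sig_max.copy()
    it = 0
    n_eval = 1
    stop = j0 <= cfg.cost_threshold
    for _ in range(cfg.n_sweeps):
        if stop:
            break
        for l in range(p):
            if stop:
                break
            for _ in range(cfg.iters_per_param):
                cand = theta.copy()
                std = np.sqrt(sig[l])
                for _ in range(100):
                    v = theta[l] + rng.normal(0.0, std)
                    if cfg.lo[l] <= v <= cfg.hi[l]:
                        break
                cand[l] = min(max(v, cfg.lo[l]), cfg.hi[l])
                j = cost(cand)
                j = np.inf if np.isnan(j) else float(j)
                n_eval += 1
                if j < best_cost[it]:
                    theta = cand
                    sig[l] = cfg.sig_max[l]
                    accepted[it] = True
                    new_cost = j
                else:
                    sig[l] = sig[l] / cfg.contr[l]
                    if sig[l] < cfg.sig_min[l]:
                        sig[l] = cfg.sig_max[l]
                    new_cost = best_cost[it]
                best_theta[it + 1] = theta
                best_cost[it + 1] = new_cost
                variances[it] = sig
                it += 1
                if new_cost <= cfg.cost_threshold:
                    stop = True
                    break
    return ARSTrace(param_names=cfg.param_names,
                    best_theta=best_theta[:it + 1],
                    best_cost=best_cost[:it + 1],
                    variances=variances[:it],
                    accepted=accepted[:it],
                    n_evaluations=n_eval)


def ars_estimate_report(trace: ARSTrace, theta_star: ParameterSet) -> dict:
    """Per-parameter NQE curves and the final estimate of an ARS run.

    Returns a dict with ``nqe_curves`` (DataFrame, one column per
    parameter, one row per iteration), ``final_theta`` and ``final_nqe``.
    """
    star = np.array([getattr(theta_star, k) for k in trace.param_names])
    if np.any(star == 0):
        raise ZeroDivisionError("reference parameter values must be nonzero")
    curves = ((trace.best_theta - star) / star) ** 2
    df = pd.DataFrame(curves, columns=list(trace.param_names))
    df.index.name = "iteration"
    final = trace.final_parameter_set(theta_star)
    return {
        "nqe_curves": df,
        "final_theta": dict(zip(trace.param_names, trace.final_theta)),
        "final_nqe": nqe(final, theta_star, which=trace.param_names),
    }
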