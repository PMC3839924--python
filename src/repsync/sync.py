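"""Driven secondary system and the synchronization-error cost.

All three estimators in this package minimize (or threshold) the same
quantity: the time-averaged squared discrepancy between two scalar channels
observed from the *primary* network and the matching channels of a model
copy — the *secondary* system — that is diffusively driven by those
observations.  When the adjustable parameters of the secondary system equal
the true ones and the coupling coefficient D exceeds the synchronization
threshold D_c, the secondary locks onto the primary and the distance drops
to (numerically) zero; a parameter mismatch leaves a residual error that
grows with the mismatch.  Estimating initial conditions is unnecessary: the
drive erases them after a transient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _core
from .integrate import DEFAULT_DT, DEFAULT_TRANSIENT, integrate_network
from .model import (
    N_STATE, PARAM_NAMES, STATE_NAMES, ParameterSet,
    default_initial_state, validate_params,
)

__all__ = [
    "CouplingSpec", "CostConfig", "ObservationSet", "secondary_rhs",
    "simulate_observations", "sync_distance", "extended_distance", "nqe",
    "add_observation_noise", "noise_floor", "SyncCost",
    "find_coupling_threshold", "EXTENDED_CHANNELS",
]

#: channels of the 8-channel (extended) observation mode: the full state of
#: cell 1 plus the first variable of cell 2.
EXTENDED_CHANNELS = (0, 1, 2, 3, 4, 5, 6, 7)

DEFAULT_D = 5.0


@dataclass(frozen=True)
class CouplingSpec:
    """How the secondary system is driven.

    observed_channels : state indices whose primary time series are observed
        and injected; the default (0, 7) is the first variable (tetR mRNA)
        of each cell.  The matching secondary equations receive the additive
        diffusive term D*(u_k(t) - y_k(t)); all other equations are untouched.
    D : coupling coefficient (1/t.u.), fixed for a whole experiment.
    """

    observed_channels: tuple = (0, 7)
    D: float = DEFAULT_D

    def __post_init__(self):
        chans = tuple(int(c) for c in self.observed_channels)
        object.__setattr__(self, "observed_channels", chans)
        if len(chans) == 0 or len(set(chans)) != len(chans):
            raise ValueError("observed_channels must be distinct and non-empty")
        if any(not 0 <= c < N_STATE for c in chans):
            raise ValueError("observed channel index out of range")
        if self.D < 0:
            raise ValueError("D must be non-negative")

    def validate(self) -> list[str]:
        """Violations of the canonical two-channel, one-per-cell layout."""
        bad = []
        if len(self.observed_channels) != 2:
            bad.append("expected exactly two observed channels")
        else:
            cells = sorted(c // 7 for c in self.observed_channels)
            if cells != [0, 1]:
                bad.append("expected one observed channel per cell")
        return bad


@dataclass(frozen=True)
class CostConfig:
    """Window over which the synchronization error is accumulated.

    T : observation window (t.u.) entering the average;
    transient : initial stretch (t.u.) discarded so the secondary forgets
        its initial condition;
    sample_step : spacing of the cost samples (t.u.), a multiple of the
        integration step;
    extended : accumulate the error over the eight extended channels
        instead of the two coupling channels.
    """

    T: float = 50.0
    transient: float = 50.0
    sample_step: float = 0.05
    extended: bool = False

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.transient < 0:
            raise ValueError("transient must be non-negative")
        if self.sample_step <= 0:
            raise ValueError("sample_step must be positive")

    @property
    def total_time(self) -> float:
        return self.transient + self.T


@dataclass
class ObservationSet:
    """Sampled scalar channels from the primary system.

    ``channels[k, j]`` is state component ``channel_indices[j]`` at time
    ``times[k]``; the grid is regular.  ``noise_sigma`` records the standard
    deviation of any added observation noise (0 for clean data).
    """

    times: np.ndarray
    channels: np.ndarray
    channel_indices: tuple
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or len(self.times) != len(self.channels):
            raise ValueError("channels must be (len(times), n_channels)")
        if self.channels.shape[1] != len(self.channel_indices):
            raise ValueError("channel_indices mismatch")
        if len(self.times) > 1:
            gaps = np.diff(self.times)
            if not np.allclose(gaps, gaps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("observation grid must be regular")
        self.channel_indices = tuple(int(c) for c in self.channel_indices)

    @property
    def sample_step(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def column(self, state_index: int) -> np.ndarray:
        """Series of the observed channel holding the given state index."""
        try:
            j = self.channel_indices.index(state_index)
        except ValueError:
            raise KeyError(f"state index {state_index} is not observed") from None
        return self.channels[:, j]

    def to_csv(self, path) -> None:
        """CSV with a ``time`` column plus one named column per channel;
        ``noise_sigma`` goes into a JSON sidecar ``<path>.meta.json``."""
        path = Path(path)
        df = pd.DataFrame(
            self.channels, columns=[STATE_NAMES[i] for i in self.channel_indices])
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)
        sidecar = {"noise_sigma": self.noise_sigma,
                   "channel_indices": list(self.channel_indices)}
        Path(f"{path}.meta.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = Path(f"{path}.meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            idx = tuple(meta["channel_indices"])
            sigma = float(meta["noise_sigma"])
        else:
            idx = tuple(STATE_NAMES.index(c) for c in df.columns if c != "time")
            sigma = 0.0
        return cls(times=df["time"].to_numpy(),
                   channels=df.drop(columns="time").to_numpy(),
                   channel_indices=idx, noise_sigma=sigma)


def secondary_rhs(y, theta_hat: ParameterSet, u_t, spec: CouplingSpec) -> np.ndarray:
    """dy/dt of the driven secondary system at state ``y``.

    ``u_t`` holds the observed channel values at the current time, in the
    order of ``spec.observed_channels``.  Identical functional form to the
    primary system plus D*(u_k - y_k) on each coupled equation.
    """
    from .model import primary_rhs
    u_t = np.atleast_1d(np.asarray(u_t, dtype=float))
    if u_t.shape != (len(spec.observed_channels),):
        raise ValueError("u_t must match the number of observed channels")
    dy = primary_rhs(y, theta_hat)
    for j, k in enumerate(spec.observed_channels):
        dy[k] += spec.D * (u_t[j] - y[k])
    return dy


def _draw_initial_state(rng) -> np.ndarray:
    """Random initial condition from the same box as the shipped default:
    mRNA/protein components uniform in [0, 50], AI components in [0, 5]."""
    x0 = np.empty(N_STATE)
    for i in range(2):
        o = 7 * i
        x0[o:o + 6] = rng.uniform(0.0, 50.0, size=6)
        x0[o + 6] = rng.uniform(0.0, 5.0)
    return x0


def simulate_observations(theta_star: ParameterSet, x0=None,
                          cfg: CostConfig = CostConfig(),
                          spec: CouplingSpec = CouplingSpec(),
                          seed=None, dt=DEFAULT_DT,
                          primary_transient=DEFAULT_TRANSIENT,
                          method="heun") -> ObservationSet:
    """Generate the observed data by integrating the primary system.

    The primary network is integrated from ``x0`` (drawn from the standard
    initial-condition box using ``seed`` when not given) for
    ``primary_transient + cfg.transient + cfg.T`` t.u.; the first
    ``primary_transient`` t.u. are discarded, time is reset to zero, and the
    observed channels are sampled every ``cfg.sample_step``.  With
    ``cfg.extended`` the eight extended channels are recorded; the coupling
    channels are always among them.
    """
    bad = validate_params(theta_star)
    if bad:
        raise ValueError("invalid parameters: " + "; ".join(bad))
    if x0 is None:
        rng = np.random.default_rng(seed)
        x0 = _draw_initial_state(rng)
    chans = EXTENDED_CHANNELS if cfg.extended else spec.observed_channels
    stride = int(round(cfg.sample_step / dt))
    if not np.isclose(stride * dt, cfg.sample_step, rtol=1e-9):
        raise ValueError("sample_step must be a multiple of dt")
    t_total = primary_transient + cfg.total_time
    times, samples, diverged = integrate_network(
        theta_star, x0, dt, t_total, sample_every=stride,
        channels=list(chans), method=method)
    if diverged:
        raise RuntimeError("primary trajectory diverged")
    keep = times >= primary_transient - 1e-9
    return ObservationSet(times=times[keep] - primary_transient,
                          channels=samples[keep], channel_indices=chans)


def add_observation_noise(obs: ObservationSet, sigma: float,
                          seed=None) -> ObservationSet:
    """Add i.i.d. zero-mean Gaussian noise of std ``sigma`` to every sample."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return ObservationSet(obs.times.copy(), obs.channels.copy(),
                              obs.channel_indices, noise_sigma=0.0)
    rng = np.random.default_rng(seed)
    noisy = obs.channels + rng.normal(0.0, sigma, size=obs.channels.shape)
    return ObservationSet(obs.times.copy(), noisy, obs.channel_indices,
                          noise_sigma=float(sigma))


def noise_floor(sigma: float) -> float:
    """Lower bound of the two-channel distance under observation noise of
    std ``sigma``: twice the noise variance, 2*sigma**2."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return 2.0 * sigma ** 2


def _distance(theta_hat, obs, spec, cfg, y0, dt, err_channels, method="heun"):
    if validate_params(theta_hat):
        return np.inf
    if y0 is None:
        y0 = default_initial_state()
    y0 = np.asarray(y0, dtype=float)
    n_steps = int(round(cfg.total_time / dt))
    if obs.times[-1] < cfg.total_time - 1e-9:
        raise ValueError("observations do not cover the cost window")
    grid = np.arange(n_steps + 1) * dt
    u = np.column_stack([np.interp(grid, obs.times, obs.column(c))
                         for c in spec.observed_channels])
    stride = int(round(cfg.sample_step / dt))
    if not np.isclose(stride * dt, cfg.sample_step, rtol=1e-9):
        raise ValueError("sample_step must be a multiple of dt")
    first = int(np.ceil(round(cfg.transient / dt, 9)))
    first = ((first + stride - 1) // stride) * stride
    sample_idx = np.arange(first, n_steps + 1, stride, dtype=np.int64)
    out_idx = np.asarray(err_channels, dtype=np.int64)
    cidx = np.asarray(spec.observed_channels, dtype=np.int64)
    samples, _, div_at = _core.rk2_drive(
        y0, theta_hat.to_array(), dt, n_steps, u, cidx, spec.D,
        sample_idx, out_idx, midpoint=(method == "midpoint"))
    if div_at >= 0:
        return np.inf
    # observed values at the sampled grid times, per error channel
    err = 0.0
    for j, c in enumerate(err_channels):
        u_obs = np.interp(sample_idx * dt, obs.times, obs.column(c))
        err += np.sum((u_obs - samples[:, j]) ** 2)
    return float(err / len(sample_idx))


def sync_distance(theta_hat: ParameterSet, obs: ObservationSet,
                  spec: CouplingSpec = CouplingSpec(),
                  cfg: CostConfig = CostConfig(), y0=None,
                  dt=DEFAULT_DT, method="heun") -> float:
    """Synchronization error of the secondary system driven by ``obs``.

    The secondary system is integrated from ``y0`` over the full
    observation window, the first ``cfg.transient`` t.u. are discarded and
    the returned value is the average over the sampled times of the summed
    squared differences between observed and secondary values on the
    observed channels.  A diverged secondary trajectory yields ``+inf``.
    """
    return _distance(theta_hat, obs, spec, cfg, y0, dt,
                     spec.observed_channels, method)


def extended_distance(theta_hat: ParameterSet, obs8: ObservationSet,
                      spec: CouplingSpec = CouplingSpec(),
                      cfg: CostConfig = CostConfig(), y0=None,
                      dt=DEFAULT_DT, method="heun") -> float:
    """Eight-channel variant of :func:`sync_distance`.

    The squared error is accumulated over the extended channel set (full
    state of cell 1 plus the first variable of cell 2) while the coupling
    still acts only through the two coupled equations.
    """
    missing = [c for c in EXTENDED_CHANNELS if c not in obs8.channel_indices]
    if missing:
        raise ValueError(f"extended distance needs channels {EXTENDED_CHANNELS}")
    return _distance(theta_hat, obs8, spec, cfg, y0, dt,
                     EXTENDED_CHANNELS, method)


def nqe(theta_hat: ParameterSet, theta_star: ParameterSet,
        which=None) -> dict:
    """Normalized quadratic error per parameter: ((th - th*)/th*)**2."""
    names = tuple(which) if which is not None else PARAM_NAMES
    out = {}
    for name in names:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        ref = getattr(theta_star, name)
        if ref == 0:
            raise ZeroDivisionError(f"reference value of {name} is zero")
        out[name] = float(((getattr(theta_hat, name) - ref) / ref) ** 2)
    return out


class SyncCost:
    """Callable cost over a subset of parameters, with evaluation counting.

    ``cost(values)`` embeds ``values`` (ordered as ``param_names``) into
    ``base_theta`` and returns the synchronization distance against the
    stored observations.  Every call increments ``n_calls`` — one secondary
    integration per call, the complexity currency of all estimators.
    """

    def __init__(self, obs: ObservationSet, param_names,
                 base_theta: ParameterSet = None,
                 spec: CouplingSpec = CouplingSpec(),
                 cfg: CostConfig = CostConfig(), y0=None, dt=DEFAULT_DT,
                 method="heun"):
        self.obs = obs
        self.param_names = tuple(param_names)
        self.base_theta = base_theta or ParameterSet()
        self.spec = spec
        self.cfg = cfg
        self.y0 = default_initial_state() if y0 is None else np.asarray(y0, float)
        self.dt = dt
        self.method = method
        self.n_calls = 0

    def theta(self, values) -> ParameterSet:
        return self.base_theta.replace(
            **dict(zip(self.param_names, (float(v) for v in values))))

    def __call__(self, values) -> float:
        self.n_calls += 1
        theta = self.theta(values)
        fn = extended_distance if self.cfg.extended else sync_distance
        return fn(theta, self.obs, self.spec, self.cfg,
                  self.y0, self.dt, self.method)


def find_coupling_threshold(theta: ParameterSet, obs: ObservationSet,
                            d_grid, cfg: CostConfig = CostConfig(),
                            channels=(0, 7), y0=None, dt=DEFAULT_DT,
                            tol=1e-3) -> float:
    """Smallest D on ``d_grid`` at which the identical-parameter secondary
    synchronizes (distance below ``tol``); NaN if none does."""
    for d in sorted(float(v) for v in d_grid):
        spec = CouplingSpec(observed_channels=channels, D=d)
        if sync_distance(theta, obs, spec, cfg, y0, dt) < tol:
            return d
    return float("nan")
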