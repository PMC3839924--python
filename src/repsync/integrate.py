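"""Fixed-step second-order Runge-Kutta integration and bifurcation scans.

Two integration paths share the same stepping rule:

* :func:`rk2_integrate` — a generic integrator for any Python right-hand
  side, used for oracle checks and for driving arbitrary systems;
* a compiled fast path for the 14-dimensional repressilator network
  (:mod:`repsync._core`), used by the bifurcation scans and by the
  synchronization-cost machinery, where millions of steps are taken.

The default stepping variant is Heun's method (full Euler predictor,
trapezoidal corrector); the explicit midpoint variant is available through
``method="midpoint"``.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _core
from .model import N_STATE, STATE_NAMES, ParameterSet, PARAM_NAMES

__all__ = ["Trajectory", "rk2_integrate", "local_maxima", "bifurcation_scan"]

DEFAULT_DT = 0.01
DEFAULT_TRANSIENT = 100.0


@dataclass
class Trajectory:
    """Regularly sampled solution of an ODE system.

    ``states[k]`` is the state at ``times[k]``; ``diverged`` flags a run in
    which a state component became non-finite (stored states past that
    point are NaN).
    """

    times: np.ndarray
    states: np.ndarray
    dt: float
    diverged: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) > 1:
            gaps = np.diff(self.times)
            if not np.allclose(gaps, self.dt, rtol=1e-9, atol=1e-12):
                raise ValueError("times must be equally spaced with spacing dt")

    def channel(self, index: int) -> np.ndarray:
        return self.states[:, index]

    def to_csv(self, path) -> None:
        names = (STATE_NAMES if self.states.shape[1] == N_STATE
                 else [f"x{i}" for i in range(self.states.shape[1])])
        df = pd.DataFrame(self.states, columns=list(names))
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        times = df["time"].to_numpy()
        states = df.drop(columns="time").to_numpy()
        dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
        diverged = bool(np.any(~np.isfinite(states)))
        return cls(times=times, states=states, dt=dt, diverged=diverged)


def _wrap_rhs(rhs):
    """Accept rhs(x), rhs(x, t) or, with a drive, rhs(x, t, u)."""
    try:
        n_args = len(inspect.signature(rhs).parameters)
    except (TypeError, ValueError):
        n_args = 2
    return n_args


def rk2_integrate(rhs, x0, dt, t_end, drive=None, method="heun") -> Trajectory:
    """Integrate ``rhs`` from ``x0`` over [0, t_end] with fixed step ``dt``.

    Parameters
    ----------
    rhs : callable
        ``rhs(x)``, ``rhs(x, t)`` or — when ``drive`` is given —
        ``rhs(x, t, u)`` where ``u`` is the drive evaluated at the stage time.
    drive : callable or None
        Time-indexed external signal ``drive(t)``; it must cover
        ``[0, t_end]`` (evaluated at stage times up to ``t_end``).
    method : ``"heun"`` or ``"midpoint"``
        RK2 variant; Heun is the shipped default.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if method not in ("heun", "midpoint"):
        raise ValueError("method must be 'heun' or 'midpoint'")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    n_steps = int(round(t_end / dt))

    n_args = _wrap_rhs(rhs)
    if drive is None:
        def f(x, t):
            return np.asarray(rhs(x) if n_args == 1 else rhs(x, t))
    else:
        def f(x, t):
            return np.asarray(rhs(x, t, drive(t)))

    states = np.empty((n_steps + 1, x0.size))
    states[0] = x0
    x = x0.copy()
    diverged = False
    for k in range(n_steps):
        t = k * dt
        if not np.all(np.isfinite(x)):
            states[k:] = np.nan
            diverged = True
            break
        k1 = f(x, t)
        if method == "heun":
            k2 = f(x + dt * k1, t + dt)
            x = x + 0.5 * dt * (k1 + k2)
        else:
            k2 = f(x + 0.5 * dt * k1, t + 0.5 * dt)
            x = x + dt * k2
        states[k + 1] = x
    else:
        if not np.all(np.isfinite(x)):
            diverged = True
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times=times, states=states, dt=dt, diverged=diverged)


def integrate_network(theta: ParameterSet, x0, dt, t_end, sample_every=1,
                      channels=None, method="heun"):
    """Fast path: integrate the repressilator network with the compiled core.

    Returns ``(times, samples, diverged)`` where ``samples`` holds the
    requested ``channels`` (default: all 14) every ``sample_every`` steps.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x0 = np.asarray(x0, dtype=float)
    n_steps = int(round(t_end / dt))
    sample_idx = np.arange(0, n_steps + 1, sample_every, dtype=np.int64)
    out_idx = (np.arange(N_STATE, dtype=np.int64) if channels is None
               else np.asarray(channels, dtype=np.int64))
    samples, _, div_at = _core.rk2_free(
        x0, theta.to_array(), dt, n_steps, sample_idx, out_idx,
        midpoint=(method == "midpoint"))
    times = sample_idx * dt
    return times, samples, div_at >= 0


def local_maxima(series) -> np.ndarray:
    """Values of strict local maxima: v[k-1] < v[k] > v[k+1].

    Plateaus are excluded by the strict inequalities; series shorter than 3
    return an empty array.
    """
    v = np.asarray(series, dtype=float)
    if v.size < 3:
        return np.empty(0)
    mask = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return v[1:-1][mask]


def bifurcation_scan(control, values, base: ParameterSet,
                     transient=DEFAULT_TRANSIENT, window=200.0,
                     channel=0, x0=None, dt=DEFAULT_DT, method="heun"):
    """Maxima of one state channel versus a control parameter.

    For every grid value the control parameter is set on a copy of ``base``,
    the network is integrated from the *same* fixed initial condition for
    ``transient + window`` t.u., the transient is discarded and the strict
    local maxima of the chosen channel over the window are collected.

    Returns a dict mapping grid value -> array of maxima, or ``None`` for
    grid values at which the trajectory diverged.
    """
    if control not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {control!r}")
    if window <= 0:
        raise ValueError("window must be positive")
    from .model import default_initial_state
    if x0 is None:
        x0 = default_initial_state()
    out = {}
    n_skip = int(round(transient / dt))
    for v in np.asarray(values, dtype=float):
        theta = base.replace(**{control: float(v)})
        _, samples, diverged = integrate_network(
            theta, x0, dt, transient + window, channels=[channel],
            method=method)
        if diverged:
            out[float(v)] = None
            continue
        out[float(v)] = local_maxima(samples[n_skip:, 0])
    return out
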