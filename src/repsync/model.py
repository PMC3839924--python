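"""Two-cell modified-repressilator network with quorum-sensing coupling.

Each cell is a three-gene ring oscillator (tetR -| cI -| lacI -| tetR)
extended with a quorum-sensing feedback loop: the autoinducer (AI) molecule
diffuses through the cell membrane and activates a second copy of *lacI*.
Because AI synthesis is placed under control of the repressilator protein CI,
the cell-to-cell coupling is phase-repulsive, which makes the two-cell
network multistable and, in the parameter window shipped as the reference
set, chaotic.

The extracellular AI is eliminated by a quasi-steady-state approximation;
its influence is summarized by the single coupling-strength parameter
``Q`` in [0, 1].  The dimensionless state has 14 components in the fixed
order ``(a1, b1, c1, A1, B1, C1, S1, a2, b2, c2, A2, B2, C2, S2)``:
per cell, mRNA of tetR/cI/lacI, proteins TetR/CI/LacI, intracellular AI.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from . import _core

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "N_STATE",
    "ParameterSet",
    "reference_chaotic_params",
    "default_initial_state",
    "external_ai",
    "primary_rhs",
    "validate_params",
]

PARAM_NAMES = ("alpha", "kappa", "n", "beta", "ks0", "ks1", "eta", "Q")

STATE_NAMES = (
    "a1", "b1", "c1", "A1", "B1", "C1", "S1",
    "a2", "b2", "c2", "A2", "B2", "C2", "S2",
)

N_STATE = _core.N_STATE


@dataclass(frozen=True)
class ParameterSet:
    """Dimensionless parameter vector of the two-cell network.

    alpha : transcription rate in the absence of repressor
    kappa : maximum transcription rate of the LuxR promoter (AI activation)
    n     : Hill coefficient of transcriptional repression
    beta  : mRNA-to-protein lifetime ratio (shared by all three proteins)
    ks0   : intracellular AI degradation rate (1/t.u.)
    ks1   : AI synthesis rate, proportional to CI level (1/t.u.)
    eta   : membrane diffusion coefficient of the AI (1/t.u.)
    Q     : extracellular coupling strength, in [0, 1]
    """

    alpha: float = 216.0
    kappa: float = 20.0
    n: float = 2.6
    beta: float = 0.85
    ks0: float = 1.0
    ks1: float = 0.01
    eta: float = 2.0
    Q: float = 0.35

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParameterSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, (float(v) for v in arr))))

    def replace(self, **kw) -> "ParameterSet":
        unknown = set(kw) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls(**{k: float(v) for k, v in json.loads(text).items()})


def validate_params(theta: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty list means valid)."""
    bad = []
    for k in PARAM_NAMES:
        v = getattr(theta, k)
        if not math.isfinite(v):
            bad.append(f"{k} must be finite")
    for k in ("alpha", "kappa", "ks0", "ks1", "eta"):
        if getattr(theta, k) < 0:
            bad.append(f"{k} must be non-negative")
    if not theta.n > 0:
        bad.append("n must be positive")
    if not theta.beta > 0:
        bad.append("beta must be positive")
    if not 0.0 <= theta.Q <= 1.0:
        bad.append("Q outside [0,1]")
    return bad


def reference_chaotic_params() -> ParameterSet:
    """Parameter set in the chaotic window used as ground truth everywhere.

    alpha=216, kappa=20, n=2.6, beta=0.85, ks0=1, ks1=0.01, eta=2, Q=0.35;
    at these values the attractor has a positive largest Lyapunov exponent
    and the bifurcation scans show broad bands of distinct maxima.
    """
    return ParameterSet()


def default_initial_state() -> np.ndarray:
    """Fixed, deliberately cell-asymmetric initial condition.

    The network is symmetric under cell exchange, so a symmetric initial
    state would stay on the (non-chaotic) synchronous manifold forever; the
    shipped default breaks the symmetry.
    """
    return np.array(
        [0.0, 10.0, 0.0, 40.0, 0.0, 10.0, 0.0,
         10.0, 0.0, 5.0, 0.0, 30.0, 0.0, 0.5])


def external_ai(s1: float, s2: float, q: float) -> float:
    """Quasi-steady-state extracellular AI: S_e = Q * (S1 + S2) / 2."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("Q outside [0,1]")
    return q * 0.5 * (s1 + s2)


def primary_rhs(x, theta: ParameterSet) -> np.ndarray:
    """dx/dt of the autonomous (primary) two-cell network at state ``x``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (N_STATE,):
        raise ValueError(f"state must have {N_STATE} components, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite components")
    out = np.empty(N_STATE)
    _core.rhs(x, theta.to_array(), out)
    return out
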