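"""Numba kernels for the two-cell repressilator network and its driven copy.

The state layout is fixed everywhere in the package as

    (a1, b1, c1, A1, B1, C1, S1, a2, b2, c2, A2, B2, C2, S2)

i.e. per cell: three mRNA levels (tetR, cI, lacI), three protein levels
(TetR, CI, LacI) and the intracellular autoinducer S.  The parameter vector
is ordered (alpha, kappa, n, beta, ks0, ks1, eta, Q).
"""

import numpy as np
from numba import njit

N_STATE = 14
N_PARAM = 8


@njit(cache=True)
def rhs(x, p, out):
    """Time derivative of the two-cell network, written into ``out``.

    Repression cycle per cell: LacI (C) represses tetR (a), TetR (A)
    represses cI (b), CI (B) represses lacI (c).  lacI additionally carries
    the quorum-sensing activation term kappa*S/(1+S); the autoinducer S is
    produced proportionally to CI, degrades, and diffuses against the
    quasi-steady-state extracellular level S_e = Q*(S1+S2)/2.
    """
    alpha = p[0]
    kappa = p[1]
    n = p[2]
    beta = p[3]
    ks0 = p[4]
    ks1 = p[5]
    eta = p[6]
    q = p[7]
    s_e = q * 0.5 * (x[6] + x[13])
    for i in range(2):
        o = 7 * i
        a = x[o]
        b = x[o + 1]
        c = x[o + 2]
        pa = x[o + 3]
        pb = x[o + 4]
        pc = x[o + 5]
        s = x[o + 6]
        out[o] = -a + alpha / (1.0 + pc ** n)
        out[o + 1] = -b + alpha / (1.0 + pa ** n)
        out[o + 2] = -c + alpha / (1.0 + pb ** n) + kappa * s / (1.0 + s)
        out[o + 3] = beta * (a - pa)
        out[o + 4] = beta * (b - pb)
        out[o + 5] = beta * (c - pc)
        out[o + 6] = -ks0 * s + ks1 * pb - eta * (s - s_e)


@njit(cache=True)
def rk2_drive(x0, p, dt, n_steps, u, cidx, d_coupling, sample_idx, out_idx,
              midpoint):
    """Fixed-step explicit RK2 with optional diffusive drive on ``cidx``.

    u : (n_steps + 1, len(cidx)) drive samples on the integration grid; the
        coupling adds d_coupling * (u_k(t) - x_k(t)) to equation cidx[k].
        Pass a (1, 0) array and empty cidx for the undriven (primary) system.
    sample_idx : sorted step indices at which out_idx components are stored.
    midpoint : False -> Heun (full Euler predictor, trapezoidal corrector),
        True -> explicit midpoint.

    Returns (samples, final_state, diverged_at); diverged_at is the step at
    which a non-finite component was first seen, or -1.  Samples past the
    divergence stay NaN.
    """
    x = x0.copy()
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    xs = np.empty(N_STATE)
    nc = cidx.shape[0]
    n_samp = sample_idx.shape[0]
    out = np.full((n_samp, out_idx.shape[0]), np.nan)
    si = 0
    diverged_at = -1
    for step in range(n_steps + 1):
        ok = True
        for j in range(N_STATE):
            if not np.isfinite(x[j]):
                ok = False
        if not ok:
            diverged_at = step
            break
        if si < n_samp and sample_idx[si] == step:
            for j in range(out_idx.shape[0]):
                out[si, j] = x[out_idx[j]]
            si += 1
        if step == n_steps:
            break
        rhs(x, p, k1)
        for j in range(nc):
            k1[cidx[j]] += d_coupling * (u[step, j] - x[cidx[j]])
        if midpoint:
            for j in range(N_STATE):
                xs[j] = x[j] + 0.5 * dt * k1[j]
            rhs(xs, p, k2)
            for j in range(nc):
                k2[cidx[j]] += d_coupling * (
                    0.5 * (u[step, j] + u[step + 1, j]) - xs[cidx[j]])
            for j in range(N_STATE):
                x[j] = x[j] + dt * k2[j]
        else:
            for j in range(N_STATE):
                xs[j] = x[j] + dt * k1[j]
            rhs(xs, p, k2)
            for j in range(nc):
                k2[cidx[j]] += d_coupling * (u[step + 1, j] - xs[cidx[j]])
            for j in range(N_STATE):
                x[j] = x[j] + 0.5 * dt * (k1[j] + k2[j])
    return out, x, diverged_at


_EMPTY_U = np.zeros((1, 0))
_EMPTY_IDX = np.zeros(0, dtype=np.int64)


def rk2_free(x0, p, dt, n_steps, sample_idx, out_idx, midpoint=False):
    """Undriven wrapper around :func:`rk2_drive` (primary system)."""
    u = np.zeros((n_steps + 1, 0))
    return rk2_drive(x0, p, dt, n_steps, u, _EMPTY_IDX, 0.0,
                     sample_idx, out_idx, midpoint)
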