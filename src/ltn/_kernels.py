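"""Compiled inner loops for the Gibbs samplers.

These kernels mirror the reference numpy implementations in
:mod:`ltn.glasso` and :mod:`ltn.model` exactly (same full conditionals);
they exist because the column sweep of the graphical-lasso update and the
per-sample multivariate-normal draws dominate the sampler runtime.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _inv_gauss(mu, lam):
    # Michael-Schucany-Haas transform method, written in the
    # cancellation-free form x = 4 mu^2 lam y / (mu y + s)^2 with
    # s = sqrt(mu y (mu y + 4 lam)), stable even for very large mu
    y = np.random.standard_normal() ** 2
    if y == 0.0:
        return mu
    my = mu * y
    s = math.sqrt(my * (my + 4.0 * lam))
    x = 4.0 * mu * mu * lam * y / (my + s) ** 2
    if np.random.random() > mu / (mu + x):
        x = mu * mu / x
    return x


@njit(cache=True)
def _forward_solve(L, b):
    d = b.size
    x = np.empty(d)
    for i in range(d):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _back_solve_t(L, b):
    # solves L^T x = b for lower-triangular L
    d = b.size
    x = np.empty(d)
    for i in range(d - 1, -1, -1):
        s = b[i]
        for k in range(i + 1, d):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def glasso_sweep(Omega, S, n, lam, seed):
    """One column-wise block Gibbs sweep of the graphical-lasso posterior.

    Maintains Sigma = Omega^{-1} through partitioned-inverse identities so
    each column costs O(d^2) plus one (d-1) Cholesky.  Latent Laplace
    scales are refreshed per column: 1/tau ~ InvGauss(lam/|omega|, lam^2).
    Returns a new Omega (positive definite by construction).
    """
    d = Omega.shape[0]
    Omega = Omega.copy()
    Sigma = np.linalg.inv(Omega)
    for a in range(d):
        for b in range(a + 1, d):
            v = 0.5 * (Sigma[a, b] + Sigma[b, a])
            Sigma[a, b] = v
            Sigma[b, a] = v
    np.random.seed(seed)
    dm = d - 1
    others = np.empty(dm, dtype=np.int64)
    O11_inv = np.empty((dm, dm))
    Cinv = np.empty((dm, dm))
    lin = np.empty(dm)
    for j in range(d):
        t = 0
        for a in range(d):
            if a != j:
                others[t] = a
                t += 1
        s22 = S[j, j]
        sjj = Sigma[j, j]
        for a in range(dm):
            ia = others[a]
            sa = Sigma[ia, j]
            for b in range(dm):
                ib = others[b]
                O11_inv[a, b] = Sigma[ia, ib] - sa * Sigma[ib, j] / sjj
        for a in range(dm):
            for b in range(dm):
                Cinv[a, b] = (s22 + lam) * 0.5 * (O11_inv[a, b] + O11_inv[b, a])
            w = abs(Omega[others[a], j])
            if w < 1e-12:
                w = 1e-12
            Cinv[a, a] += _inv_gauss(lam / w, lam * lam)
            lin[a] = -S[others[a], j]
        gamma = np.random.gamma(n / 2.0 + 1.0, 2.0 / (s22 + lam))
        L = np.linalg.cholesky(Cinv)
        u = _forward_solve(L, lin)
        for a in range(dm):
            u[a] += np.random.standard_normal()
        beta = _back_solve_t(L, u)
        # ob = inv(Omega_11) beta, then refresh Omega and Sigma
        quad = 0.0
        for a in range(dm):
            s = 0.0
            for b in range(dm):
                s += 0.5 * (O11_inv[a, b] + O11_inv[b, a]) * beta[b]
            lin[a] = s  # reuse buffer as ob
            quad += s * beta[a]
        ojj = gamma + quad
        for a in range(dm):
            Omega[others[a], j] = beta[a]
            Omega[j, others[a]] = beta[a]
        Omega[j, j] = ojj
        for a in range(dm):
            ia = others[a]
            for b in range(dm):
                ib = others[b]
                Sigma[ia, ib] = 0.5 * (O11_inv[a, b] + O11_inv[b, a]) \
                    + lin[a] * lin[b] / gamma
            Sigma[ia, j] = -lin[a] / gamma
            Sigma[j, ia] = -lin[a] / gamma
        Sigma[j, j] = 1.0 / gamma
    return Omega


@njit(cache=True)
def mvn_prec_batch(Omega, diag_add, lin, seed):
    """Draw x_i ~ MVN(P_i^{-1} lin_i, P_i^{-1}) with P_i = Omega + diag(diag_add_i)
    for i = 1..n, via per-row Cholesky and triangular solves."""
    n, d = diag_add.shape
    out = np.empty((n, d))
    P = np.empty((d, d))
    np.random.seed(seed)
    for i in range(n):
        for a in range(d):
            for b in range(d):
                P[a, b] = Omega[a, b]
            P[a, a] += diag_add[i, a]
        L = np.linalg.cholesky(P)
        u = _forward_solve(L, lin[i].copy())
        for a in range(d):
            u[a] += np.random.standard_normal()
        out[i] = _back_solve_t(L, u)
    return out
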