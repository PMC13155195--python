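"""Polya-Gamma random variates.

PG(b, c) is the tilted infinite convolution of gammas

    w ~ (1/(2 pi^2)) sum_k g_k / ((k - 1/2)^2 + c^2/(4 pi^2)),  g_k ~ Gamma(b, 1)

whose key property is that binomial-logistic likelihoods become Gaussian in
the log-odds once w is conditioned on.  For b = 1 we implement Devroye's
exact alternating-series rejection sampler (the standard one used for
logistic data augmentation); integer b is drawn as a sum of b independent
PG(1, c) variates, which is exact.

The Gibbs samplers additionally use a moment-matched Gaussian for very
large b (default b > 64): the PG(b, c) law is itself a b-fold convolution,
so by that point its skewness is O(b^{-1/2}) and the Gaussian error is far
below Monte-Carlo noise.  The public scalar ``pg_draw`` never approximates.

Moment identities used throughout as correctness oracles:

    E[w]   = (b / 2c) tanh(c/2)            (limit b/4 at c = 0)
    Var[w] = b (sinh c - c) / (4 c^3 cosh^2(c/2))   (limit b/24 at c = 0)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["pg_draw", "pg_draw_matrix", "pg_mean", "pg_var"]

_TRUNC = 0.64  # series switch point of the Devroye sampler


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _coef(n, x):
    # n-th term of the alternating series for the J*(1, z) density at x
    if x <= _TRUNC:
        return (math.pi * (n + 0.5)
                * (2.0 / (math.pi * x)) ** 1.5
                * math.exp(-2.0 * (n + 0.5) ** 2 / x))
    return (math.pi * (n + 0.5)
            * math.exp(-((n + 0.5) ** 2) * math.pi ** 2 * x / 2.0))


@njit(cache=True)
def _mass_texpon(z):
    # P(choose the truncated-exponential proposal branch), cf. the mixture
    # envelope of Devroye's sampler
    t = _TRUNC
    fz = math.pi ** 2 / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    cb = _norm_cdf(b)
    ca = _norm_cdf(a)
    xb = 0.0
    if cb > 0.0:
        xb = math.exp(x0 - z + math.log(cb))
    xa = 0.0
    if ca > 0.0:
        xa = math.exp(x0 + z + math.log(ca))
    qdivp = 4.0 / math.pi * (xb + xa)
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rt_inv_gauss(z, t):
    # inverse-Gaussian IG(1/z, 1) truncated to (0, t)
    if z < 1.0 / t:
        # rejection from the one-sided stable-like envelope
        while True:
            e1 = -math.log(np.random.random())
            e2 = -math.log(np.random.random())
            while e1 * e1 > 2.0 * e2 / t:
                e1 = -math.log(np.random.random())
                e2 = -math.log(np.random.random())
            x = t / (1.0 + t * e1) ** 2
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = np.random.standard_normal() ** 2
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def _pg1(c):
    """One exact PG(1, c) draw (Devroye alternating-series sampler)."""
    z = abs(c) / 2.0
    fz = math.pi ** 2 / 8.0 + z * z / 2.0
    p_texp = _mass_texpon(z)
    while True:
        if np.random.random() < p_texp:
            x = _TRUNC - math.log(np.random.random()) / fz
        else:
            x = _rt_inv_gauss(z, _TRUNC)
        s = _coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _coef(n, x)
                if y > s:
                    break
        if accept:
            return x / 4.0


@njit(cache=True)
def _pg_int(b, c):
    total = 0.0
    for _ in range(b):
        total += _pg1(c)
    return total


@njit(cache=True)
def _pg_moments(c):
    # per-unit (b = 1) mean and variance of PG(1, c)
    c = abs(c)
    if c < 1e-4:
        return 0.25 - c * c / 48.0, 1.0 / 24.0
    m = math.tanh(c / 2.0) / (2.0 * c)
    if c > 30.0:
        v = 1.0 / (2.0 * c ** 3)
    else:
        v = (math.sinh(c) - c) / (4.0 * c ** 3 * math.cosh(c / 2.0) ** 2)
    return m, v


@njit(cache=True)
def _pg_matrix(b, c, exact_max, seed):
    np.random.seed(seed)
    out = np.zeros(b.size)
    bf = b.ravel()
    cf = c.ravel()
    for i in range(bf.size):
        bi = bf[i]
        if bi == 0:
            continue
        ci = cf[i]
        if bi <= exact_max:
            out[i] = _pg_int(bi, ci)
        else:
            m, v = _pg_moments(ci)
            mean = bi * m
            sd = math.sqrt(bi * v)
            x = mean + sd * np.random.standard_normal()
            tries = 0
            while x <= 0.0 and tries < 100:
                x = mean + sd * np.random.standard_normal()
                tries += 1
            out[i] = x if x > 0.0 else mean
    return out.reshape(b.shape)


@njit(cache=True)
def _pg_exact_scalar(b, c, seed):
    np.random.seed(seed)
    return _pg_int(b, c)


def pg_draw(b, c, seed=None) -> float:
    """Exact PG(b, c) draw for non-negative integer b (PG(0, c) is 0).

    ``seed`` may be an int or a numpy Generator used to derive one.
    """
    if b < 0:
        raise ValueError("b must be non-negative")
    bi = int(round(b))
    if abs(b - bi) > 1e-9:
        raise ValueError("exact sampling implemented for integer b only")
    if bi == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    return float(_pg_exact_scalar(bi, float(c), int(rng.integers(1, 2 ** 31 - 1))))


def pg_draw_matrix(b, c, rng, exact_max: int = 64):
    """Elementwise PG(b_ij, c_ij) draws for an integer array b.

    Entries with b <= ``exact_max`` are exact Devroye sums; larger b use the
    moment-matched Gaussian (see module docstring).  Zero counts give w = 0
    exactly.
    """
    b = np.ascontiguousarray(b, dtype=np.int64)
    c = np.ascontiguousarray(np.broadcast_to(c, b.shape), dtype=np.float64)
    seed = int(rng.integers(1, 2 ** 31 - 1))
    return _pg_matrix(b, c, exact_max, seed)


def pg_mean(b, c):
    """E[PG(b, c)] = (b/2c) tanh(c/2), with the c -> 0 limit b/4."""
    c = np.asarray(c, dtype=float)
    out = np.where(np.abs(c) < 1e-8, 0.25, np.tanh(c / 2.0) / np.where(c == 0, 1.0, 2.0 * c))
    return b * out


def pg_var(b, c):
    """Var[PG(b, c)], with the c -> 0 limit b/24."""
    c = np.abs(np.asarray(c, dtype=float))
    small = c < 1e-4
    cs = np.where(small, 1.0, c)
    v = (np.sinh(cs) - cs) / (4.0 * cs ** 3 * np.cosh(cs / 2.0) ** 2)
    return b * np.where(small, 1.0 / 24.0, v)
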