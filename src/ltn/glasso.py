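"""Block Gibbs updates for the Bayesian graphical lasso prior.

The prior on a d x d precision matrix Omega is

    p(Omega | lam) propto prod_{j<k} DE(omega_jk | lam)
                        * prod_j Exp(omega_jj | lam/2) * 1{Omega PD},

i.e. double-exponential (Laplace) off-diagonals and exponential diagonals,
restricted to the positive-definite cone.  Combined with a Gaussian
sample scatter matrix S (sum of outer products of n centered vectors) the
posterior is sampled column-by-column: writing the Laplace as a scale
mixture of normals with exponential mixing weights tau_jk, each column's
off-diagonal block has a Gaussian full conditional and the Schur
complement of the diagonal entry a Gamma full conditional, which keeps
every update positive definite by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_glasso_precision", "sample_diagonal_precision", "init_precision"]


def init_precision(d: int) -> np.ndarray:
    return np.eye(d)


def _sample_tau_inv(Omega: np.ndarray, lam: float, rng) -> np.ndarray:
    """Latent scale update: 1/tau_jk | omega_jk ~ InvGauss(lam/|omega_jk|, lam^2)."""
    d = Omega.shape[0]
    iu = np.triu_indices(d, k=1)
    w = np.abs(Omega[iu])
    w = np.maximum(w, 1e-12)
    inv_tau_u = rng.wald(lam / w, lam * lam)
    inv_tau = np.zeros((d, d))
    inv_tau[iu] = inv_tau_u
    inv_tau += inv_tau.T
    return inv_tau


def sample_glasso_precision(
    Omega: np.ndarray,
    S: np.ndarray,
    n: int,
    lam: float,
    rng,
    use_kernel: bool = True,
) -> np.ndarray:
    """One full sweep of the column-wise block Gibbs update of Omega.

    Parameters
    ----------
    Omega : current precision matrix (modified copy is returned).
    S : scatter matrix  sum_i x_i x_i^T  of the n centered Gaussian vectors.
    n : number of vectors behind S (0 gives a prior draw sweep).
    lam : graphical-lasso rate, > 0.
    use_kernel : dispatch to the compiled sweep (same full conditionals);
        the pure-numpy path below is the reference implementation.
    """
    d = Omega.shape[0]
    if use_kernel and d > 1:
        from ._kernels import glasso_sweep
        return glasso_sweep(np.ascontiguousarray(Omega), np.ascontiguousarray(S),
                            float(n), float(lam), int(rng.integers(1, 2 ** 31 - 1)))
    if d == 1:
        # Exp(lam/2) prior on the single precision entry, Gamma likelihood
        shape = n / 2.0 + 1.0
        rate = (S[0, 0] + lam) / 2.0
        return np.array([[rng.gamma(shape, 1.0 / rate)]])
    Omega = Omega.copy()
    inv_tau = _sample_tau_inv(Omega, lam, rng)
    # Maintain Sigma = Omega^{-1}; the partitioned-inverse identity gives
    # inv(Omega_11) = Sigma_11 - sigma_12 sigma_12^T / sigma_22 in O(d^2)
    # per column, and the sampled column updates Sigma in O(d^2) as well.
    Sigma = np.linalg.inv(Omega)
    Sigma = 0.5 * (Sigma + Sigma.T)
    for j in range(d):
        idx = np.arange(d) != j
        sig12 = Sigma[idx, j]
        O11_inv = Sigma[np.ix_(idx, idx)] - np.outer(sig12, sig12) / Sigma[j, j]
        s12 = S[idx, j]
        s22 = S[j, j]
        gamma = rng.gamma(n / 2.0 + 1.0, 2.0 / (s22 + lam))
        Cinv = (s22 + lam) * O11_inv + np.diag(inv_tau[idx, j])
        Cinv = 0.5 * (Cinv + Cinv.T)
        Lc = np.linalg.cholesky(Cinv)
        # beta ~ N(-C s12, C) with C = Cinv^{-1}, drawn via triangular solves
        tmp = np.linalg.solve(Lc, -s12)
        beta = np.linalg.solve(Lc.T, tmp + rng.standard_normal(d - 1))
        ob = O11_inv @ beta
        Omega[idx, j] = beta
        Omega[j, idx] = beta
        Omega[j, j] = gamma + beta @ ob
        # refresh Sigma for the new column
        Sigma[np.ix_(idx, idx)] = O11_inv + np.outer(ob, ob) / gamma
        Sigma[idx, j] = Sigma[j, idx] = -ob / gamma
        Sigma[j, j] = 1.0 / gamma
    return Omega


def sample_diagonal_precision(
    diag: np.ndarray,
    S_diag: np.ndarray,
    n: int,
    lam: float,
    rng,
) -> np.ndarray:
    """Update of a diagonal precision (independence across coordinates):
    omega_jj ~ Gamma(n/2 + 1, (S_jj + lam)/2), matching the exponential
    Exp(lam/2) prior on the diagonal of the full model."""
    shape = n / 2.0 + 1.0
    rate = (S_diag + lam) / 2.0
    return rng.gamma(shape, 1.0 / rate)
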