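"""The logistic-tree normal (LTN) model and its blocked Gibbs sampler.

The model couples a tree-factorized multinomial with a latent Gaussian:
counts split at every interior node A of a binary tree as

    y(A_l) | y(A), theta(A)  ~  Binomial(y(A), theta(A)),
    psi(A) = logit(theta(A)),          psi ~ MVN(mu, Sigma),

so the d = K-1 node log-odds carry an unrestricted covariance.  Polya-Gamma
augmentation w(A) | y(A), psi(A) ~ PG(y(A), psi(A)) makes every full
conditional conjugate; the precision Omega = Sigma^{-1} carries a graphical
lasso prior and is updated by column-wise block Gibbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .glasso import sample_glasso_precision
from .polya_gamma import pg_draw_matrix
from .transforms import clr_transform, tlr_inverse
from .tree import BinaryTaxonomyTree, NodeCountTable, aggregate_node_counts

__all__ = [
    "LTNParams", "PosteriorDraws",
    "sample_ltn_counts", "ltn_loglik", "multinomial_loglik",
    "gibbs_fit_ltn", "induced_clr_correlation",
]


@dataclass
class LTNParams:
    """Mean and covariance of the node log-odds."""

    mu: np.ndarray     # (d,)
    Sigma: np.ndarray  # (d, d), symmetric positive definite
    lam: float = 10.0  # graphical-lasso rate used when fitting

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("Sigma shape does not match mu")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-8):
            raise ValueError("Sigma must be symmetric")
        # raises LinAlgError if not positive definite
        np.linalg.cholesky(self.Sigma + 0.0)

    @property
    def d(self) -> int:
        return self.mu.size

    @property
    def Omega(self) -> np.ndarray:
        return np.linalg.inv(self.Sigma)


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws for the base model."""

    mu: np.ndarray              # (m, d)
    Omega: np.ndarray           # (m, d, d)
    psi: np.ndarray | None      # (m, n, d) if stored
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    def mu_mean(self) -> np.ndarray:
        return self.mu.mean(axis=0)

    def Sigma_mean(self) -> np.ndarray:
        return np.mean([np.linalg.inv(O) for O in self.Omega], axis=0)

    def params_mean(self) -> LTNParams:
        return LTNParams(self.mu_mean(), self.Sigma_mean(),
                         lam=self.meta.get("lam", 10.0))


# --------------------------------------------------------------------- #
# forward simulation and likelihood
# --------------------------------------------------------------------- #

def sample_ltn_counts(
    params: LTNParams,
    tree: BinaryTaxonomyTree,
    totals,
    seed=None,
    method: str = "multinomial",
    return_psi: bool = False,
):
    """Draw an (n, K) count matrix from LTN(mu, Sigma).

    ``method="multinomial"`` maps psi to a composition and draws one
    multinomial per sample; ``method="cascade"`` draws the sequential
    binomials down the tree.  The two are the same distribution.
    """
    rng = np.random.default_rng(seed)
    totals = np.asarray(totals)
    if np.any(totals < 0):
        raise ValueError("totals must be non-negative")
    n = totals.size
    psi = rng.multivariate_normal(params.mu, params.Sigma, size=n,
                                  method="cholesky")
    if method == "multinomial":
        p = tlr_inverse(psi, tree)
        X = np.vstack([rng.multinomial(int(totals[i]), p[i]) for i in range(n)])
    elif method == "cascade":
        theta = expit(psi)
        X = np.zeros((n, tree.K), dtype=np.int64)
        y = np.zeros(tree.d, dtype=np.int64)
        for i in range(n):
            y[:] = 0
            y[0] = int(totals[i])
            for a in range(tree.d):
                yl = rng.binomial(y[a], theta[i, a])
                yr = y[a] - yl
                (lk, li), (rk, ri) = tree.children[a]
                if lk == "leaf":
                    X[i, li] = yl
                else:
                    y[li] = yl
                if rk == "leaf":
                    X[i, ri] = yr
                else:
                    y[ri] = yr
    else:
        raise ValueError(f"unknown method {method!r}")
    if return_psi:
        return X, psi
    return X


def ltn_loglik(nct: NodeCountTable, psi: np.ndarray, tree: BinaryTaxonomyTree) -> float:
    """Tree-factorized binomial log-likelihood sum_i sum_A
    log Binom(y_i(A_l) | y_i(A), logistic(psi_i(A))).

    Nodes with y(A) = 0 contribute exactly 0.  Differs from the multinomial
    log-pmf by a constant in psi (the log ratio of counting coefficients).
    """
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    y, yl = nct.y, nct.y_left
    if psi.shape != y.shape:
        raise ValueError("psi shape does not match node count table")
    coef = gammaln(y + 1) - gammaln(yl + 1) - gammaln(y - yl + 1)
    # log theta = -softplus(-psi), log(1 - theta) = -softplus(psi)
    ll = coef + yl * (-np.logaddexp(0.0, -psi)) + (y - yl) * (-np.logaddexp(0.0, psi))
    return float(ll.sum())


def multinomial_loglik(X: np.ndarray, psi: np.ndarray, tree: BinaryTaxonomyTree) -> float:
    """Multinomial log-pmf of the raw counts under p = tlr^{-1}(psi)."""
    X = np.atleast_2d(np.asarray(X))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    p = tlr_inverse(psi, tree)
    coef = gammaln(X.sum(axis=1) + 1) - gammaln(X + 1).sum(axis=1)
    return float((coef + (X * np.log(p)).sum(axis=1)).sum())


# --------------------------------------------------------------------- #
# Gibbs sampler
# --------------------------------------------------------------------- #

def _init_psi(nct: NodeCountTable) -> np.ndarray:
    """Empirical logit with half-pseudo-counts, a cheap overdispersed start."""
    theta = (nct.y_left + 0.5) / (nct.y + 1.0)
    return np.log(theta) - np.log1p(-theta)


def _sample_psi_mvn(Omega, mu, w, kappa, rng):
    """psi_i | rest ~ MVN with precision Omega + diag(w_i) and linear term
    Omega mu + kappa_i, drawn for all samples via per-row Cholesky."""
    from ._kernels import mvn_prec_batch
    lin = np.ascontiguousarray(kappa + (Omega @ mu)[None, :])
    return mvn_prec_batch(np.ascontiguousarray(Omega), np.ascontiguousarray(w),
                          lin, int(rng.integers(1, 2 ** 31 - 1)))


def _sample_mu(Omega, psi_sum, n, tau2_mu, rng):
    """mu | psi, Omega ~ MVN with precision n Omega + I/tau2 and linear
    term Omega sum_i psi_i."""
    d = psi_sum.size
    M = n * Omega + np.eye(d) / tau2_mu
    Lm = np.linalg.cholesky(M)
    u = np.linalg.solve(Lm, Omega @ psi_sum)
    return np.linalg.solve(Lm.T, u + rng.standard_normal(d))


def gibbs_fit_ltn(
    X,
    tree: BinaryTaxonomyTree,
    lam: float = 10.0,
    iters: int = 10_000,
    burn: int = 5_000,
    seed=None,
    tau2_mu: float = 100.0,
    store_psi: bool = False,
    labels: list[str] | None = None,
    pg_exact_max: int = 64,
) -> PosteriorDraws:
    """Blocked Gibbs sampler for LTN(mu, Sigma) with a graphical-lasso prior
    on Omega = Sigma^{-1} and a MVN(0, tau2_mu I) hyperprior on mu.

    Cycle: (1) w_i(A) ~ PG(y_i(A), psi_i(A)); (2) psi_i joint MVN given the
    PG weights; (3) mu conjugate MVN; (4) Omega column-wise graphical-lasso
    block Gibbs.  Nodes with zero subtree count have w = 0 and contribute no
    likelihood, so their psi is drawn from the conditional prior.
    """
    if iters <= burn or burn < 0:
        raise ValueError("need iters > burn >= 0")
    nct = X if isinstance(X, NodeCountTable) else aggregate_node_counts(X, tree, labels)
    n, d = nct.y.shape
    if d == 0:
        raise ValueError("tree has no interior nodes")
    rng = np.random.default_rng(seed)

    psi = _init_psi(nct)
    mu = psi.mean(axis=0)
    Omega = np.eye(d)
    kappa = nct.kappa

    kept = iters - burn
    mu_draws = np.empty((kept, d))
    Om_draws = np.empty((kept, d, d))
    psi_draws = np.empty((kept, n, d)) if store_psi else None

    for it in range(iters):
        w = pg_draw_matrix(nct.y, psi, rng, exact_max=pg_exact_max)
        psi = _sample_psi_mvn(Omega, mu, w, kappa, rng)
        mu = _sample_mu(Omega, psi.sum(axis=0), n, tau2_mu, rng)
        # Omega | psi, mu
        resid = psi - mu
        S = resid.T @ resid
        Omega = sample_glasso_precision(Omega, S, n, lam, rng)
        if it >= burn:
            j = it - burn
            mu_draws[j] = mu
            Om_draws[j] = Omega
            if store_psi:
                psi_draws[j] = psi
    return PosteriorDraws(
        mu=mu_draws, Omega=Om_draws, psi=psi_draws,
        meta={"iters": iters, "burn": burn, "lam": lam, "seed": seed,
              "n": n, "d": d},
    )


def induced_clr_correlation(
    fit,
    tree: BinaryTaxonomyTree,
    n_mc: int = 10_000,
    seed=None,
) -> np.ndarray:
    """Monte-Carlo estimate of the K x K clr correlation implied by the
    latent Gaussian: sample psi ~ MVN(mu, Sigma), map through the inverse
    tlr, clr-transform, and take the sample correlation.

    ``fit`` may be an :class:`LTNParams` or a :class:`PosteriorDraws` (whose
    posterior-mean parameters are used).
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    params = fit.params_mean() if isinstance(fit, PosteriorDraws) else fit
    rng = np.random.default_rng(seed)
    psi = rng.multivariate_normal(params.mu, params.Sigma, size=n_mc,
                                  method="cholesky")
    z = clr_transform(tlr_inverse(psi, tree))
    cov = np.cov(z, rowvar=False)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr


def induced_clr_covariance(fit, tree, n_mc: int = 10_000, seed=None) -> np.ndarray:
    params = fit.params_mean() if isinstance(fit, PosteriorDraws) else fit
    rng = np.random.default_rng(seed)
    psi = rng.multivariate_normal(params.mu, params.Sigma, size=n_mc,
                                  method="cholesky")
    z = clr_transform(tlr_inverse(psi, tree))
    return np.cov(z, rowvar=False)
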