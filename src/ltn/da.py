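"""Mixed-effects differential abundance analysis on tree log-odds.

For sample i with two-group label s_i in {0,1}, covariates z_i (including
an intercept) and subject label g_i, the node log-odds follow

    psi_i = alpha s_i + beta^T z_i + gamma_{g_i} + eps_i,
    eps_i(A) ~ N(0, sigma_eps^2(A)),   gamma_g ~ MVN(0, Sigma_re),

with counts split down the tree by the LTN binomials.  The group contrast
alpha carries node-wise spike-and-slab priors

    alpha(A) ~ (1 - pi(A)) delta_0 + pi(A) N(0, 1/phi_alpha),
    pi(A) ~ Beta(m, 1-m),   phi_alpha ~ Gamma(t, u),

so differential abundance at node A is the event alpha(A) != 0.  The
posterior marginal alternative probability PMAP(A) = Pr(alpha(A) != 0 | Y)
and the joint PJAP = Pr(alpha != 0 | Y) are estimated by the fraction of
Gibbs draws with the corresponding event, and nodes are reported by
thresholding PMAPs to control the posterior expected FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .glasso import sample_diagonal_precision, sample_glasso_precision
from .polya_gamma import pg_draw_matrix
from .transforms import tlr_inverse
from .tree import BinaryTaxonomyTree, NodeCountTable, aggregate_node_counts

__all__ = [
    "DADesign", "DADraws", "DASummary",
    "select_m_for_global_null", "gibbs_fit_da",
    "compute_pmap", "compute_pjap", "fdr_select",
    "posterior_predictive_counts", "da_node_table",
]


@dataclass
class DADesign:
    """Design of a two-group study: group indicator s, covariate matrix Z
    (first column should be the intercept) and subject labels g in 0..G-1."""

    s: np.ndarray  # (n,) in {0, 1}
    Z: np.ndarray  # (n, q)
    g: np.ndarray  # (n,) int subject labels

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.g = np.asarray(self.g, dtype=int)
        if not set(np.unique(self.s)) <= {0.0, 1.0}:
            raise ValueError("group indicator s must be 0/1")
        n = self.s.size
        if self.Z.shape[0] != n or self.g.size != n:
            raise ValueError("design components have inconsistent lengths")
        # relabel subjects to a dense 0..G-1 range
        _, self.g = np.unique(self.g, return_inverse=True)
        if np.linalg.matrix_rank(self.Z.T @ self.Z) < self.Z.shape[1]:
            raise ValueError("Z^T Z is singular; drop collinear covariates")

    @property
    def n(self) -> int:
        return self.s.size

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def G(self) -> int:
        return int(self.g.max()) + 1


@dataclass
class DADraws:
    """Retained Gibbs draws of the mixed-effects unknowns."""

    alpha: np.ndarray    # (m, d), exact zeros encode the spike
    beta: np.ndarray     # (m, q, d)
    gamma: np.ndarray    # (m, G, d)
    sigma2: np.ndarray   # (m, d)
    phi_alpha: np.ndarray  # (m,)
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]


@dataclass
class DASummary:
    """Node selection at a target posterior expected FDR."""

    pmap: np.ndarray
    pjap: float
    threshold: float
    selected: np.ndarray       # indices of selected nodes
    target_fdr: float
    expected_fdr: float


def select_m_for_global_null(K: int, p0_null: float) -> float:
    """Prior inclusion probability m with (1-m)^(K-1) = p0_null, so the
    prior probability that all K-1 node nulls hold is exactly p0_null."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0.0 < p0_null < 1.0:
        raise ValueError("p0_null must be in (0, 1)")
    return 1.0 - p0_null ** (1.0 / (K - 1))


# --------------------------------------------------------------------- #
# Gibbs sampler
# --------------------------------------------------------------------- #

def _update_alpha(resid1, sigma2, phi, pi, rng):
    """Spike-and-slab update of alpha given per-node group-1 residuals.

    ``resid1`` is the (n1, d) matrix of residuals of the s = 1 samples.
    Marginalizing the slab N(0, 1/phi) against the Gaussian pseudo-likelihood
    gives closed-form inclusion odds per node; returns (alpha, include).
    """
    n1, d = resid1.shape
    prec = phi + n1 / sigma2                 # (d,)
    mean = (resid1.sum(axis=0) / sigma2) / prec
    log_bf = 0.5 * (np.log(phi) - np.log(prec)) + 0.5 * mean ** 2 * prec
    logit_incl = np.log(pi) - np.log1p(-pi) + log_bf
    p_incl = expit(logit_incl)
    include = rng.random(d) < p_incl
    alpha = np.where(include, mean + rng.standard_normal(d) / np.sqrt(prec), 0.0)
    return alpha, include


def gibbs_fit_da(
    X,
    tree: BinaryTaxonomyTree,
    design: DADesign,
    m: float = 0.05,
    t: float = 2.0,
    u: float = 1.0,
    c_beta: float = 50.0,
    lam: float = 10.0,
    a_sigma: float = 2.0,
    b_sigma: float = 1.0,
    iters: int = 10_000,
    burn: int = 5_000,
    seed=None,
    diagonal_precision: bool = False,
    spike_slab: bool = True,
    labels: list[str] | None = None,
    pg_exact_max: int = 64,
) -> DADraws:
    """Blocked Gibbs sampler for the mixed-effects LTN model.

    ``spike_slab=False`` replaces the spike-and-slab on alpha with a plain
    Gaussian slab (always included), the variant used for posterior
    predictive goodness-of-fit checks.  ``diagonal_precision=True`` uses an
    independence (diagonal) precision for the random effects, a proxy for
    the Dirichlet-tree covariance structure.
    """
    if iters <= burn or burn < 0:
        raise ValueError("need iters > burn >= 0")
    nct = X if isinstance(X, NodeCountTable) else aggregate_node_counts(X, tree, labels)
    n, d = nct.y.shape
    if design.n != n:
        raise ValueError("design does not match count table rows")
    if design.G == 1:
        warnings.warn("only one subject: random-effect variance is weakly identified")
    rng = np.random.default_rng(seed)

    s = design.s
    Z = design.Z
    g = design.g
    q = design.q
    G = design.G
    is1 = s == 1.0
    n1 = int(is1.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")
    grp_mat = np.zeros((G, n))
    grp_mat[g, np.arange(n)] = 1.0
    m_g = grp_mat.sum(axis=1)                     # samples per subject

    ZtZ = Z.T @ Z
    Lz = np.linalg.cholesky(ZtZ)
    kappa = nct.kappa

    # initial state
    theta = (nct.y_left + 0.5) / (nct.y + 1.0)
    psi = np.log(theta) - np.log1p(-theta)
    alpha = np.zeros(d)
    beta = np.linalg.solve(ZtZ, Z.T @ psi)        # (q, d) least squares start
    gamma = np.zeros((G, d))
    sigma2 = np.full(d, 1.0)
    pi = np.full(d, m)
    phi = t / u
    Omega_re = np.eye(d)
    diag_re = np.ones(d)

    kept = iters - burn
    out_alpha = np.empty((kept, d))
    out_beta = np.empty((kept, q, d))
    out_gamma = np.empty((kept, G, d))
    out_sigma2 = np.empty((kept, d))
    out_phi = np.empty(kept)

    for it in range(iters):
        fixed = s[:, None] * alpha[None, :] + Z @ beta + gamma[g]
        # (1) PG weights
        w = pg_draw_matrix(nct.y, psi, rng, exact_max=pg_exact_max)
        # (2) psi: elementwise Gaussian (noise is independent across nodes)
        prec = w + 1.0 / sigma2[None, :]
        mean = (kappa + fixed / sigma2[None, :]) / prec
        psi = mean + rng.standard_normal((n, d)) / np.sqrt(prec)
        # (3)-(5) spike-and-slab group contrast
        r_alpha = psi - Z @ beta - gamma[g]
        if spike_slab:
            alpha, include = _update_alpha(r_alpha[is1], sigma2, phi, pi, rng)
            pi = rng.beta(m + include, 1.0 - m + (~include))
            k_incl = int(include.sum())
            phi = rng.gamma(t + k_incl / 2.0, 1.0 / (u + (alpha ** 2).sum() / 2.0))
        else:
            prec_a = phi + n1 / sigma2
            mean_a = (r_alpha[is1].sum(axis=0) / sigma2) / prec_a
            alpha = mean_a + rng.standard_normal(d) / np.sqrt(prec_a)
            phi = rng.gamma(t + d / 2.0, 1.0 / (u + (alpha ** 2).sum() / 2.0))
        # (6) fixed effects, node by node with the g-prior-style scaling
        r_beta = psi - s[:, None] * alpha[None, :] - gamma[g]
        scale = 1.0 / sigma2 + 1.0 / (c_beta * n)     # (d,)
        mean_b = np.linalg.solve(ZtZ, Z.T @ r_beta) / (sigma2 * scale)[None, :]
        noise = np.linalg.solve(Lz.T, rng.standard_normal((q, d)))
        beta = mean_b + noise / np.sqrt(scale)[None, :]
        # (7) subject random effects
        r_gamma = psi - s[:, None] * alpha[None, :] - Z @ beta
        sums = grp_mat @ (r_gamma / sigma2[None, :])  # (G, d)
        if diagonal_precision:
            prec_g = diag_re[None, :] + m_g[:, None] / sigma2[None, :]
            gamma = sums / prec_g + rng.standard_normal((G, d)) / np.sqrt(prec_g)
            diag_re = sample_diagonal_precision(
                diag_re, (gamma ** 2).sum(axis=0), G, lam, rng)
        else:
            from ._kernels import mvn_prec_batch
            diag_add = np.ascontiguousarray(m_g[:, None] / sigma2[None, :])
            gamma = mvn_prec_batch(np.ascontiguousarray(Omega_re), diag_add,
                                   np.ascontiguousarray(sums),
                                   int(rng.integers(1, 2 ** 31 - 1)))
            Omega_re = sample_glasso_precision(Omega_re, gamma.T @ gamma, G, lam, rng)
        # (8) node noise variances
        eps = psi - s[:, None] * alpha[None, :] - Z @ beta - gamma[g]
        rate = b_sigma + 0.5 * (eps ** 2).sum(axis=0)
        sigma2 = rate / rng.gamma(a_sigma + n / 2.0, 1.0, size=d)
        if it >= burn:
            j = it - burn
            out_alpha[j] = alpha
            out_beta[j] = beta
            out_gamma[j] = gamma
            out_sigma2[j] = sigma2
            out_phi[j] = phi
    return DADraws(
        alpha=out_alpha, beta=out_beta, gamma=out_gamma, sigma2=out_sigma2,
        phi_alpha=out_phi,
        meta={"iters": iters, "burn": burn, "seed": seed, "m": m,
              "c_beta": c_beta, "lam": lam, "t": t, "u": u,
              "diagonal_precision": diagonal_precision,
              "spike_slab": spike_slab, "n": n, "d": d, "G": G},
    )


# --------------------------------------------------------------------- #
# posterior summaries and selection
# --------------------------------------------------------------------- #

def compute_pmap(draws: DADraws) -> np.ndarray:
    """PMAP(A): fraction of retained draws with alpha(A) != 0."""
    if draws.n_draws < 1:
        raise ValueError("no retained draws")
    return (draws.alpha != 0.0).mean(axis=0)


def compute_pjap(draws: DADraws) -> float:
    """PJAP: fraction of retained draws with any alpha(A) != 0."""
    if draws.n_draws < 1:
        raise ValueError("no retained draws")
    return float((draws.alpha != 0.0).any(axis=1).mean())


def fdr_select(pmap: np.ndarray, c: float) -> DASummary:
    """Report the largest PMAP-thresholded node set whose posterior expected
    FDR, the mean of (1 - PMAP) over reported nodes, stays below c.

    Sort PMAPs descending as p_1 >= ... >= p_d and take
    k = max{k : (1/k) sum_{i<=k} (1 - p_i) <= c}; all nodes with
    PMAP >= p_k are selected (ties included).  If no k qualifies nothing is
    selected.
    """
    if not 0.0 < c < 1.0:
        raise ValueError("target FDR must be in (0, 1)")
    pmap = np.asarray(pmap, dtype=float)
    order = np.argsort(-pmap, kind="stable")
    sorted_p = pmap[order]
    cum_fdr = np.cumsum(1.0 - sorted_p) / np.arange(1, pmap.size + 1)
    ok = np.flatnonzero(cum_fdr <= c)
    if ok.size == 0:
        return DASummary(pmap=pmap, pjap=np.nan, threshold=np.inf,
                         selected=np.array([], dtype=int), target_fdr=c,
                         expected_fdr=0.0)
    k = ok[-1] + 1
    threshold = sorted_p[k - 1]
    selected = np.flatnonzero(pmap >= threshold)
    exp_fdr = float((1.0 - pmap[selected]).mean())
    return DASummary(pmap=pmap, pjap=np.nan, threshold=float(threshold),
                     selected=selected, target_fdr=c, expected_fdr=exp_fdr)


def da_node_table(draws: DADraws, tree: BinaryTaxonomyTree) -> pd.DataFrame:
    """Per-node report: PMAP, posterior mean and sign of alpha.  A positive
    sign means the left child gained relative abundance in group 1."""
    pmap = compute_pmap(draws)
    mean_alpha = draws.alpha.mean(axis=0)
    rows = []
    for i in range(tree.d):
        leaves = [tree.leaf_labels[j] for j in np.flatnonzero(tree.node_mask[i])]
        rows.append({
            "node": tree.node_name(i),
            "n_leaves": len(leaves),
            "pmap": pmap[i],
            "alpha_mean": mean_alpha[i],
            "sign": "+" if mean_alpha[i] > 0 else ("-" if mean_alpha[i] < 0 else "0"),
            "leaves": ";".join(sorted(leaves)),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# posterior predictive checks
# --------------------------------------------------------------------- #

@dataclass
class PPCResult:
    """Zero-proportion envelopes from replicated posterior predictive counts."""

    otu_zero: np.ndarray      # (n_rep, K) per-OTU zero proportions
    sample_zero: np.ndarray   # (n_rep, n) per-sample zero proportions
    otu_lo: np.ndarray
    otu_hi: np.ndarray
    sample_lo: np.ndarray
    sample_hi: np.ndarray

    def otu_coverage(self, X_obs: np.ndarray) -> float:
        obs = (np.asarray(X_obs) == 0).mean(axis=0)
        return float(((obs >= self.otu_lo) & (obs <= self.otu_hi)).mean())

    def sample_coverage(self, X_obs: np.ndarray) -> float:
        obs = (np.asarray(X_obs) == 0).mean(axis=1)
        return float(((obs >= self.sample_lo) & (obs <= self.sample_hi)).mean())


def posterior_predictive_counts(
    draws: DADraws,
    design: DADesign,
    totals,
    tree: BinaryTaxonomyTree,
    n_rep: int = 500,
    seed=None,
) -> PPCResult:
    """Replicate the count table from retained posterior draws.

    Each replicate picks a retained draw, rebuilds the node log-odds means
    alpha s + Z beta + gamma, adds N(0, sigma_eps^2) noise, inverts the tlr
    and draws multinomials at the observed depths; 95% envelopes of per-OTU
    and per-sample zero proportions are returned.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    rng = np.random.default_rng(seed)
    totals = np.asarray(totals, dtype=np.int64)
    n = totals.size
    K = tree.K
    otu_zero = np.empty((n_rep, K))
    sample_zero = np.empty((n_rep, n))
    for r in range(n_rep):
        j = int(rng.integers(draws.n_draws))
        mean = (design.s[:, None] * draws.alpha[j][None, :]
                + design.Z @ draws.beta[j]
                + draws.gamma[j][design.g])
        psi = mean + rng.standard_normal(mean.shape) * np.sqrt(draws.sigma2[j])[None, :]
        p = tlr_inverse(psi, tree)
        X = np.vstack([rng.multinomial(int(totals[i]), p[i]) for i in range(n)])
        otu_zero[r] = (X == 0).mean(axis=0)
        sample_zero[r] = (X == 0).mean(axis=1)
    lo, hi = np.percentile(otu_zero, [2.5, 97.5], axis=0)
    slo, shi = np.percentile(sample_zero, [2.5, 97.5], axis=0)
    return PPCResult(otu_zero=otu_zero, sample_zero=sample_zero,
                     otu_lo=lo, otu_hi=hi, sample_lo=slo, sample_hi=shi)
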