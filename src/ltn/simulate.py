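"""Synthetic data generators and evaluation utilities.

Covers the benchmark conditions used to study the model: logistic-normal
data on ilr coordinates with hub / block / sparse precision structures,
Dirichlet-tree multinomial data, two-group signal injection for
differential-abundance power studies, a longitudinal cohort generator with
subject random effects, zero-proportion summaries, and the four-loss
comparison of estimated versus true clr correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .transforms import clr_transform, ilr_inverse
from .tree import BinaryTaxonomyTree

__all__ = [
    "PrecisionModelSpec", "gen_precision",
    "LNDataset", "simulate_ln_dataset",
    "DTMParams", "simulate_dtm_dataset", "dtm_clr_correlation",
    "inject_signal", "injection_node_effects",
    "LossReport", "loss_suite",
    "zero_proportion_stats", "ks_distance",
    "sparsity_sweep", "simulate_da_cohort",
]


# --------------------------------------------------------------------- #
# precision-matrix models
# --------------------------------------------------------------------- #

@dataclass
class PrecisionModelSpec:
    """Ground-truth precision structure for logistic-normal simulations.

    ``hub``: a few hub coordinates densely connected to the rest;
    ``block``: equally sized blocks, dense within and sparser between;
    ``sparse``: a small dense-ish random block embedded in an identity.
    Non-zero off-diagonals are +-0.3 (hub/block) or uniform +-[0.5, 1]
    (sparse); diagonals are set by strict diagonal dominance (absolute row
    sum of off-diagonals plus 0.1) so the matrix is positive definite by
    construction.
    """

    model: str            # "hub" | "block" | "sparse"
    d: int
    seed: int | None = None
    n_hubs: int = 3
    p_hub: float = 0.7
    p_offhub: float = 0.2
    n_blocks: int = 10
    p_within: float = 0.5
    p_between: float = 0.2
    magnitude: float = 0.3
    sparse_edge_p: float = 0.3
    sparse_block_factor: float = 3.0   # p1 = floor(factor * sqrt(d))


def _dominant_diagonal(Omega: np.ndarray) -> np.ndarray:
    off = np.abs(Omega).sum(axis=1) - np.abs(np.diag(Omega))
    np.fill_diagonal(Omega, off + 0.1)
    return Omega


def gen_precision(spec: PrecisionModelSpec) -> np.ndarray:
    """Generate a symmetric positive definite precision matrix."""
    d = spec.d
    if d < 2:
        raise ValueError("d must be >= 2")
    rng = np.random.default_rng(spec.seed)
    Omega = np.zeros((d, d))
    iu = np.triu_indices(d, k=1)
    if spec.model == "hub":
        hubs = rng.choice(d, size=spec.n_hubs, replace=False)
        is_hub = np.zeros(d, dtype=bool)
        is_hub[hubs] = True
        hub_pair = is_hub[iu[0]] | is_hub[iu[1]]
        p_edge = np.where(hub_pair, spec.p_hub, spec.p_offhub)
        edges = rng.random(iu[0].size) < p_edge
        vals = spec.magnitude * rng.choice([-1.0, 1.0], size=iu[0].size)
        Omega[iu] = edges * vals
    elif spec.model == "block":
        block = np.floor(np.arange(d) * spec.n_blocks / d).astype(int)
        same = block[iu[0]] == block[iu[1]]
        p_edge = np.where(same, spec.p_within, spec.p_between)
        edges = rng.random(iu[0].size) < p_edge
        vals = spec.magnitude * rng.choice([-1.0, 1.0], size=iu[0].size)
        Omega[iu] = edges * vals
    elif spec.model == "sparse":
        p1 = min(d, int(np.floor(spec.sparse_block_factor * np.sqrt(d))))
        B = np.zeros((d, d))
        iu1 = np.triu_indices(p1, k=1)
        mag = rng.uniform(0.5, 1.0, size=iu1[0].size)
        sign = rng.choice([-1.0, 1.0], size=iu1[0].size)
        edges = rng.random(iu1[0].size) < spec.sparse_edge_p
        B[iu1] = edges * mag * sign
        Omega[:p1, :p1] = B[:p1, :p1]
    else:
        raise ValueError(f"unknown precision model {spec.model!r}")
    Omega = Omega + Omega.T
    Omega = _dominant_diagonal(Omega)
    if spec.model == "sparse":
        # identity outside the dense block keeps the graph strictly sparse
        p1 = min(d, int(np.floor(spec.sparse_block_factor * np.sqrt(d))))
        for j in range(p1, d):
            Omega[j, j] = 1.0
    return Omega


# --------------------------------------------------------------------- #
# logistic-normal (ilr) simulation
# --------------------------------------------------------------------- #

@dataclass
class LNDataset:
    X: np.ndarray              # (n, K) counts
    m: np.ndarray              # (d,) true ilr mean
    Omega0: np.ndarray         # (d, d) true ilr precision
    eta: np.ndarray            # (n, d) latent balances
    true_clr_corr: np.ndarray  # (K, K)
    meta: dict = field(default_factory=dict)


def true_clr_corr_from_ilr(Omega0: np.ndarray, tree: BinaryTaxonomyTree) -> np.ndarray:
    """clr of an ilr-Gaussian composition is exactly V^T eta, so the clr
    covariance is V^T Omega0^{-1} V (closed form, no Monte Carlo)."""
    V = tree.ilr_basis()
    cov = V.T @ np.linalg.inv(Omega0) @ V
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr


def simulate_ln_dataset(
    tree: BinaryTaxonomyTree,
    Omega0: np.ndarray,
    n: int = 200,
    total: int = 100_000,
    seed=None,
    mean_sd: float = 4.0,
) -> LNDataset:
    """Counts from a logistic-normal on the tree's ilr coordinates:
    eta_i ~ MVN(m, Omega0^{-1}), p_i = ilr^{-1}(eta_i),
    X_i ~ Multinomial(total, p_i), with the components of m drawn
    independently from N(0, mean_sd^2) (default variance 16)."""
    rng = np.random.default_rng(seed)
    d = tree.d
    if Omega0.shape != (d, d):
        raise ValueError("Omega0 does not match tree dimension")
    m = rng.normal(0.0, mean_sd, size=d)
    Sigma0 = np.linalg.inv(Omega0)
    eta = rng.multivariate_normal(m, Sigma0, size=n, method="cholesky")
    p = ilr_inverse(eta, tree)
    X = np.vstack([rng.multinomial(total, p[i]) for i in range(n)])
    return LNDataset(
        X=X, m=m, Omega0=Omega0, eta=eta,
        true_clr_corr=true_clr_corr_from_ilr(Omega0, tree),
        meta={"n": n, "total": total, "seed": seed},
    )


# --------------------------------------------------------------------- #
# Dirichlet-tree multinomial simulation
# --------------------------------------------------------------------- #

@dataclass
class DTMParams:
    """Independent Beta branching: theta(A) ~ Beta(mu(A) nu(A), (1-mu(A)) nu(A))."""

    mu_A: np.ndarray
    nu_A: np.ndarray

    def __post_init__(self):
        self.mu_A = np.asarray(self.mu_A, dtype=float)
        self.nu_A = np.asarray(self.nu_A, dtype=float)
        if np.any((self.mu_A <= 0) | (self.mu_A >= 1)):
            raise ValueError("mu_A must lie in (0, 1)")
        if np.any(self.nu_A <= 0):
            raise ValueError("nu_A must be positive")


def _dtm_compositions(dtm: DTMParams, tree: BinaryTaxonomyTree, n: int, rng):
    theta = rng.beta(dtm.mu_A * dtm.nu_A, (1.0 - dtm.mu_A) * dtm.nu_A, size=(n, tree.d))
    theta = np.clip(theta, 1e-12, 1.0 - 1e-12)
    logp = np.log(theta) @ tree.left_mask + np.log1p(-theta) @ tree.right_mask
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def simulate_dtm_dataset(
    tree: BinaryTaxonomyTree,
    dtm: DTMParams,
    n: int = 200,
    total: int = 100_000,
    seed=None,
    return_p: bool = False,
):
    """Counts from the Dirichlet-tree multinomial: independent Beta branch
    probabilities at every interior node, then one multinomial per sample."""
    rng = np.random.default_rng(seed)
    p = _dtm_compositions(dtm, tree, n, rng)
    X = np.vstack([rng.multinomial(total, p[i]) for i in range(n)])
    return (X, p) if return_p else X


def dtm_clr_correlation(dtm: DTMParams, tree: BinaryTaxonomyTree,
                        n_mc: int = 50_000, seed=None) -> np.ndarray:
    """Monte-Carlo clr correlation of DTM compositions (no closed form)."""
    rng = np.random.default_rng(seed)
    p = _dtm_compositions(dtm, tree, n_mc, rng)
    z = clr_transform(p)
    cov = np.cov(z, rowvar=False)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr


# --------------------------------------------------------------------- #
# two-group signal injection
# --------------------------------------------------------------------- #

def inject_signal(
    X_base: np.ndarray,
    groups: np.ndarray,
    K_star: int,
    a_star: float,
    candidate_taxa=None,
    seed=None,
):
    """Multiply the counts of K_star randomly chosen candidate taxa by
    (1 + a_star) in group-1 samples (rounded to the nearest integer).

    By default the candidates are the 20 taxa with highest mean per-sample
    relative abundance.  Returns (modified counts, selected taxon indices).
    """
    X = np.asarray(X_base)
    groups = np.asarray(groups)
    if a_star < 0:
        raise ValueError("a_star must be >= 0")
    if not np.any(groups == 1) or not np.any(groups == 0):
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    if candidate_taxa is None:
        rel = X / np.maximum(X.sum(axis=1, keepdims=True), 1)
        candidate_taxa = np.argsort(-rel.mean(axis=0))[:20]
    candidate_taxa = np.asarray(candidate_taxa)
    if K_star > candidate_taxa.size:
        raise ValueError("K_star exceeds the candidate pool")
    chosen = rng.choice(candidate_taxa, size=K_star, replace=False)
    out = X.astype(np.int64).copy()
    rows = np.flatnonzero(groups == 1)
    out[np.ix_(rows, chosen)] = np.rint(
        out[np.ix_(rows, chosen)] * (1.0 + a_star)).astype(np.int64)
    return out, np.sort(chosen)


def injection_node_effects(
    tree: BinaryTaxonomyTree,
    base_composition: np.ndarray,
    taxa: np.ndarray,
    a_star: float,
) -> np.ndarray:
    """True node-level log-odds shifts induced by multiplying the given taxa
    of a reference composition by (1 + a_star): the difference of branch
    logits before and after.  Nodes whose subtree misses the injected taxa
    shift by exactly zero."""
    p0 = np.asarray(base_composition, dtype=float)
    p0 = p0 / p0.sum()
    p1 = p0.copy()
    p1[np.asarray(taxa)] *= (1.0 + a_star)
    # no renormalization: branch logits are scale-invariant, and skipping it
    # keeps unaffected subtrees at exactly zero shift

    def logits(p):
        mass = p @ tree.node_mask.T
        left = p @ tree.left_mask.T
        return np.log(left) - np.log(mass - left)

    return logits(p1) - logits(p0)


# --------------------------------------------------------------------- #
# losses and zero-pattern summaries
# --------------------------------------------------------------------- #

@dataclass
class LossReport:
    """Four matrix losses between an estimated and a true clr correlation:
    Frobenius, operator L1 (max absolute column sum), entrywise L-infinity,
    and spectral (largest singular value)."""

    frobenius: float
    l1: float
    linf: float
    spectral: float

    def as_dict(self) -> dict:
        return {"frobenius": self.frobenius, "l1": self.l1,
                "linf": self.linf, "spectral": self.spectral}


def loss_suite(est_corr: np.ndarray, true_corr: np.ndarray) -> LossReport:
    est = np.asarray(est_corr, dtype=float)
    true = np.asarray(true_corr, dtype=float)
    if est.shape != true.shape:
        raise ValueError("matrices must have the same shape")
    diff = est - true
    return LossReport(
        frobenius=float(np.linalg.norm(diff, "fro")),
        l1=float(np.abs(diff).sum(axis=0).max()),
        linf=float(np.abs(diff).max()),
        spectral=float(np.linalg.norm(diff, 2)),
    )


def zero_proportion_stats(X: np.ndarray):
    """Per-OTU (column) and per-sample (row) zero fractions."""
    X = np.atleast_2d(np.asarray(X))
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    return (X == 0).mean(axis=0), (X == 0).mean(axis=1)


def ks_distance(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov distance between empirical
    distributions (e.g. of per-taxon zero proportions)."""
    return float(ks_2samp(np.asarray(a), np.asarray(b)).statistic)


# --------------------------------------------------------------------- #
# sparsity sweep
# --------------------------------------------------------------------- #

def sparsity_sweep(
    mu_hat: np.ndarray,
    Sigma_hat: np.ndarray,
    mean_scales,
    var_scales,
    tree: BinaryTaxonomyTree,
    totals,
    seed=None,
):
    """Zero-proportion response to scaling the latent mean or the marginal
    variances (correlation held fixed) of an LTN generator.

    Returns a list of records, one per (kind, scale), each holding the
    per-OTU and per-sample zero-proportion vectors of a dataset generated
    at that scale.  Scale 1 in either grid reproduces the baseline.
    """
    from .model import LTNParams, sample_ltn_counts

    mu_hat = np.asarray(mu_hat, dtype=float)
    Sigma_hat = np.asarray(Sigma_hat, dtype=float)
    sd = np.sqrt(np.diag(Sigma_hat))
    corr = Sigma_hat / np.outer(sd, sd)
    rng = np.random.default_rng(seed)
    records = []
    for scale in var_scales:
        if scale <= 0:
            raise ValueError("scales must be positive")
        s_sd = sd * np.sqrt(scale)
        Sigma_s = corr * np.outer(s_sd, s_sd)
        X = sample_ltn_counts(LTNParams(mu_hat, Sigma_s), tree, totals,
                              seed=rng.integers(2 ** 31 - 1))
        oz, sz = zero_proportion_stats(X)
        records.append({"kind": "variance", "scale": float(scale),
                        "otu_zero": oz, "sample_zero": sz})
    for scale in mean_scales:
        if scale <= 0:
            raise ValueError("scales must be positive")
        X = sample_ltn_counts(LTNParams(mu_hat * scale, Sigma_hat), tree, totals,
                              seed=rng.integers(2 ** 31 - 1))
        oz, sz = zero_proportion_stats(X)
        records.append({"kind": "mean", "scale": float(scale),
                        "otu_zero": oz, "sample_zero": sz})
    return records


# --------------------------------------------------------------------- #
# longitudinal cohort generator for DA experiments
# --------------------------------------------------------------------- #

def simulate_da_cohort(
    tree: BinaryTaxonomyTree,
    G: int = 33,
    per_subject: int = 10,
    mu=None,
    mu_sd: float = 1.5,
    sd_re: float = 0.7,
    sd_eps: float = 0.7,
    total_log_mean: float = np.log(30_000.0),
    total_log_sd: float = 1.0,
    seed=None,
):
    """A synthetic longitudinal cohort with subject-level random effects.

    Node log-odds for sample i of subject g are
    psi_i = mu + gamma_g + eps_i with gamma_g ~ N(0, sd_re^2 I) and
    eps_i ~ N(0, sd_eps^2 I); sequencing depths are log-normal.  The
    defaults mimic a 16S infant-cohort scale: 33 subjects with about 10
    samples each and median depth 30k.  Returns (X, subject labels, totals,
    psi).
    """
    rng = np.random.default_rng(seed)
    d = tree.d
    if mu is None:
        mu = rng.normal(0.0, mu_sd, size=d)
    mu = np.asarray(mu, dtype=float)
    n = G * per_subject
    g = np.repeat(np.arange(G), per_subject)
    gamma = rng.normal(0.0, sd_re, size=(G, d))
    psi = mu[None, :] + gamma[g] + rng.normal(0.0, sd_eps, size=(n, d))
    totals = np.maximum(
        rng.lognormal(total_log_mean, total_log_sd, size=n).astype(np.int64), 100)
    logp = (-np.logaddexp(0.0, -psi)) @ tree.left_mask \
        + (-np.logaddexp(0.0, psi)) @ tree.right_mask
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    X = np.vstack([rng.multinomial(int(totals[i]), p[i]) for i in range(n)])
    return X, g, totals, psi
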