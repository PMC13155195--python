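"""Log-ratio transforms of compositions: tlr, ilr and clr.

The tree-based log-ratio (tlr) maps a composition to the vector of
left-branch log-odds at the interior nodes of a binary tree,

    psi(A) = logit( mass(A_l) / mass(A) ),

and is the coordinate system of the logistic-tree normal model.  The ilr
balance at a node contrasts geometric means of the left and right subtree
probabilities with the usual orthonormal scaling; clr is the centered
log-ratio.  All transforms accept a single composition or a stack of rows.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .tree import BinaryTaxonomyTree

__all__ = [
    "tlr_forward", "tlr_inverse",
    "ilr_forward", "ilr_inverse",
    "clr_transform", "clr_inverse",
]


def _as2d(p):
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    return (p[None, :] if single else p), single


def _check_positive(p, what="composition"):
    if np.any(p < 0):
        raise ValueError(f"{what} has negative entries")
    if np.any(p == 0):
        raise ValueError(
            f"{what} has zero entries; log-ratio transforms require strictly "
            "positive input"
        )


def tlr_forward(p, tree: BinaryTaxonomyTree, pseudo_mass: bool = False):
    """Node log-odds psi(A) = logit(theta(A)), theta = left mass / node mass.

    With ``pseudo_mass=True`` an epsilon of 1e-10 of the total is added to
    every leaf before transforming, so zero-laden empirical compositions can
    be mapped; by default zero subtree mass is an error.
    """
    p, single = _as2d(p)
    if p.shape[-1] != tree.K:
        raise ValueError("composition length does not match tree leaves")
    if pseudo_mass:
        p = p + 1e-10 * p.sum(axis=-1, keepdims=True)
    if np.any(p < 0):
        raise ValueError("composition has negative entries")
    mass = p @ tree.node_mask.T
    left = p @ tree.left_mask.T
    if np.any(mass <= 0) or np.any(left <= 0) or np.any(mass - left <= 0):
        raise ValueError(
            "zero subtree mass: tlr undefined (pass pseudo_mass=True to add "
            "an epsilon)"
        )
    psi = np.log(left) - np.log(mass - left)
    return psi[0] if single else psi


def tlr_inverse(psi, tree: BinaryTaxonomyTree):
    """Composition with p_j the product of branch probabilities along the
    root-to-leaf path; exact inverse of :func:`tlr_forward`."""
    psi = np.asarray(psi, dtype=float)
    single = psi.ndim == 1
    if single:
        psi = psi[None, :]
    if psi.shape[-1] != tree.d:
        raise ValueError("psi length does not match interior nodes")
    # log theta = -softplus(-psi), log(1-theta) = -softplus(psi)
    log_theta = -np.logaddexp(0.0, -psi)
    log_1m = -np.logaddexp(0.0, psi)
    logp = log_theta @ tree.left_mask + log_1m @ tree.right_mask
    p = np.exp(logp)
    p /= p.sum(axis=-1, keepdims=True)  # remove rounding drift
    return p[0] if single else p


def clr_transform(p):
    """Centered log-ratio: log(p_j / g(p)).  Scale-invariant, zero-sum."""
    p, single = _as2d(p)
    _check_positive(p)
    lp = np.log(p)
    out = lp - lp.mean(axis=-1, keepdims=True)
    return out[0] if single else out


def clr_inverse(x):
    x, single = _as2d(x)
    p = np.exp(x - logsumexp(x, axis=-1, keepdims=True))
    return p[0] if single else p


def ilr_forward(p, tree: BinaryTaxonomyTree):
    """Tree-structured ilr balances

        eta(A) = sqrt(|A_l||A_r| / (|A_l|+|A_r|)) * log( g(p(A_l)) / g(p(A_r)) )

    where g is the geometric mean over the leaves of a subtree.
    Equivalently eta = V clr(p) for the orthonormal contrast matrix V of
    the tree's sequential binary partition.
    """
    p, single = _as2d(p)
    if p.shape[-1] != tree.K:
        raise ValueError("composition length does not match tree leaves")
    _check_positive(p)
    eta = clr_transform(p) @ tree.ilr_basis().T
    return eta[0] if single else eta


def ilr_inverse(eta, tree: BinaryTaxonomyTree):
    """Inverse balances: p proportional to exp(V^T eta)."""
    eta = np.asarray(eta, dtype=float)
    single = eta.ndim == 1
    if single:
        eta = eta[None, :]
    if eta.shape[-1] != tree.d:
        raise ValueError("eta length does not match interior nodes")
    p = clr_inverse(eta @ tree.ilr_basis())
    return p[0] if single else p


def ilr_forward_geometric(p, tree: BinaryTaxonomyTree):
    """Direct evaluation of the balance formula via subtree geometric means
    (reference implementation; agrees with :func:`ilr_forward`)."""
    p, single = _as2d(p)
    _check_positive(p)
    lp = np.log(p)
    L, R = tree.left_mask, tree.right_mask
    l = L.sum(axis=1).astype(float)
    r = R.sum(axis=1).astype(float)
    log_gl = (lp @ L.T) / l
    log_gr = (lp @ R.T) / r
    eta = np.sqrt(l * r / (l + r)) * (log_gl - log_gr)
    return eta[0] if single else eta
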