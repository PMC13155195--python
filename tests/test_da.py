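import numpy as np
import pytest
from scipy.special import expit

from ltn.da import (
    DADesign,
    DADraws,
    _update_alpha,
    compute_pjap,
    compute_pmap,
    da_node_table,
    fdr_select,
    gibbs_fit_da,
    posterior_predictive_counts,
    select_m_for_global_null,
)
from ltn.transforms import tlr_inverse
from ltn.tree import random_binary_tree


def _draws_from_alpha(alpha):
    m, d = alpha.shape
    return DADraws(alpha=alpha, beta=np.zeros((m, 1, d)),
                   gamma=np.zeros((m, 1, d)), sigma2=np.ones((m, d)),
                   phi_alpha=np.ones(m))


class TestPriorCalibration:
    def test_two_taxa_half_null(self):
        assert select_m_for_global_null(2, 0.5) == pytest.approx(0.5)

    def test_inverts_global_null_probability(self, rng):
        for _ in range(50):
            K = int(rng.integers(2, 500))
            p0 = float(rng.uniform(0.01, 0.99))
            m = select_m_for_global_null(K, p0)
            assert abs((1 - m) ** (K - 1) - p0) < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            select_m_for_global_null(1, 0.5)
        with pytest.raises(ValueError):
            select_m_for_global_null(10, 1.0)


class TestPosteriorProbabilities:
    def test_counting_example(self):
        alpha = np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        draws = _draws_from_alpha(alpha)
        np.testing.assert_allclose(compute_pmap(draws), [0.5, 0.5])
        assert compute_pjap(draws) == pytest.approx(0.75)

    def test_all_null_draws(self):
        draws = _draws_from_alpha(np.zeros((10, 3)))
        assert not compute_pmap(draws).any()
        assert compute_pjap(draws) == 0.0

    def test_pjap_dominates_pmap(self, rng):
        alpha = rng.normal(size=(200, 6)) * (rng.random((200, 6)) < 0.3)
        draws = _draws_from_alpha(alpha)
        assert compute_pjap(draws) >= compute_pmap(draws).max()


def _brute_force_select(pmap, c):
    best = np.array([], dtype=int)
    for thr in np.unique(pmap):
        sel = np.flatnonzero(pmap >= thr)
        if sel.size and (1.0 - pmap[sel]).mean() <= c and sel.size > best.size:
            best = sel
    return best


class TestFdrSelect:
    def test_hand_example(self):
        s = fdr_select(np.array([0.99, 0.98, 0.90, 0.60]), 0.05)
        assert s.threshold == pytest.approx(0.90)
        np.testing.assert_array_equal(s.selected, [0, 1, 2])
        assert s.expected_fdr == pytest.approx((0.01 + 0.02 + 0.10) / 3)

    def test_all_certain(self):
        s = fdr_select(np.ones(5), 0.05)
        assert s.selected.size == 5
        assert s.expected_fdr == 0.0

    def test_nothing_selectable(self):
        s = fdr_select(np.array([0.5]), 0.05)
        assert s.selected.size == 0

    def test_ties_at_threshold_all_selected(self):
        s = fdr_select(np.array([0.99, 0.99, 0.99, 0.2]), 0.05)
        np.testing.assert_array_equal(s.selected, [0, 1, 2])

    def test_matches_brute_force(self, rng):
        for _ in range(300):
            d = int(rng.integers(1, 21))
            pmap = rng.random(d)  # continuous, so thresholds are untied
            c = float(rng.uniform(0.01, 0.3))
            got = set(fdr_select(pmap, c).selected)
            assert got == set(_brute_force_select(pmap, c))


class TestDesign:
    def test_non_binary_group_rejected(self):
        with pytest.raises(ValueError):
            DADesign(s=[0, 2], Z=np.ones((2, 1)), g=[0, 1])

    def test_collinear_covariates_rejected(self):
        Z = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError):
            DADesign(s=[0, 1, 0, 1], Z=Z, g=[0, 0, 1, 1])

    def test_subject_relabeling_dense(self):
        d = DADesign(s=[0, 1, 0], Z=np.ones((3, 1)), g=[7, 7, 42])
        np.testing.assert_array_equal(d.g, [0, 0, 1])
        assert d.G == 2


class TestSpikeSlabUpdate:
    def test_inclusion_matches_analytic_posterior(self):
        """d=1 collapsed toy: Gibbs inclusion frequency equals the
        analytically integrated posterior inclusion probability."""
        rng = np.random.default_rng(31)
        n1, sigma2, phi, pi = 25, 1.3, 0.8, 0.25
        r1 = 0.45 + rng.normal(0, np.sqrt(sigma2), (n1, 1))
        prec = phi + n1 / sigma2
        mean = r1.sum() / sigma2 / prec
        log_bf = 0.5 * (np.log(phi) - np.log(prec)) + 0.5 * mean ** 2 * prec
        p_true = expit(np.log(pi / (1 - pi)) + log_bf)
        hits = sum(
            _update_alpha(r1, np.array([sigma2]), phi, np.array([pi]), rng)[1][0]
            for _ in range(8000)
        )
        se = np.sqrt(p_true * (1 - p_true) / 8000)
        assert abs(hits / 8000 - p_true) < 4 * se


@pytest.fixture(scope="module")
def strong_signal_fit():
    rng = np.random.default_rng(41)
    tree = random_binary_tree(8, seed=40)
    d, n = tree.d, 200
    s = rng.permutation(np.arange(n) % 2).astype(float)
    g = np.arange(n) % 10
    mu = rng.normal(0, 1, d)
    alpha = np.zeros(d)
    alpha[2] = 2.0
    gamma = rng.normal(0, 0.5, (10, d))
    psi = mu + s[:, None] * alpha + gamma[g] + rng.normal(0, 0.5, (n, d))
    p = tlr_inverse(psi, tree)
    X = np.vstack([rng.multinomial(2000, p[i]) for i in range(n)])
    design = DADesign(s=s, Z=np.ones((n, 1)), g=g)
    fit = gibbs_fit_da(X, tree, design, m=0.05, iters=1500, burn=500, seed=42)
    return tree, design, X, fit, alpha


class TestGibbsDa:
    def test_strong_node_detected(self, strong_signal_fit):
        tree, design, X, fit, alpha = strong_signal_fit
        pmap = compute_pmap(fit)
        assert pmap[2] > 0.95
        assert fit.alpha[:, 2].mean() == pytest.approx(2.0, abs=0.5)

    def test_node_table_reports_sign(self, strong_signal_fit):
        tree, design, X, fit, alpha = strong_signal_fit
        table = da_node_table(fit, tree)
        assert len(table) == tree.d
        assert table.loc[2, "sign"] == "+"
        assert table["pmap"].between(0, 1).all()

    def test_posterior_predictive_self_coverage(self, strong_signal_fit):
        tree, design, X, fit, alpha = strong_signal_fit
        ppc = posterior_predictive_counts(fit, design, X.sum(axis=1), tree,
                                          n_rep=200, seed=43)
        assert ppc.otu_coverage(X) >= 0.9
        assert ppc.sample_coverage(X) >= 0.8

    def test_ppc_zero_depth_gives_all_zero(self, strong_signal_fit):
        tree, design, X, fit, alpha = strong_signal_fit
        ppc = posterior_predictive_counts(fit, design,
                                          np.zeros(design.n, dtype=int), tree,
                                          n_rep=5, seed=44)
        np.testing.assert_array_equal(ppc.otu_zero, 1.0)
        np.testing.assert_array_equal(ppc.sample_zero, 1.0)

    def test_single_subject_warns(self):
        tree = random_binary_tree(4, seed=45)
        rng = np.random.default_rng(46)
        X = rng.integers(1, 50, size=(12, tree.K))
        design = DADesign(s=np.arange(12) % 2, Z=np.ones((12, 1)), g=np.zeros(12))
        with pytest.warns(UserWarning, match="one subject"):
            gibbs_fit_da(X, tree, design, iters=20, burn=5, seed=47)

    def test_diagonal_precision_mode_runs(self):
        tree = random_binary_tree(5, seed=48)
        rng = np.random.default_rng(49)
        X = rng.integers(0, 80, size=(30, tree.K))
        design = DADesign(s=np.arange(30) % 2, Z=np.ones((30, 1)),
                          g=np.arange(30) % 5)
        fit = gibbs_fit_da(X, tree, design, iters=60, burn=10, seed=50,
                           diagonal_precision=True)
        assert fit.alpha.shape == (50, tree.d)
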