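import numpy as np
import pytest

from ltn.simulate import (
    DTMParams,
    PrecisionModelSpec,
    gen_precision,
    inject_signal,
    injection_node_effects,
    ks_distance,
    loss_suite,
    simulate_da_cohort,
    simulate_dtm_dataset,
    simulate_ln_dataset,
    sparsity_sweep,
    true_clr_corr_from_ilr,
    zero_proportion_stats,
)
from ltn.tree import aggregate_node_counts, balanced_tree, random_binary_tree
from ltn.transforms import ilr_forward


class TestGenPrecision:
    @pytest.mark.parametrize("model", ["hub", "block", "sparse"])
    @pytest.mark.parametrize("d", [10, 49, 99])
    def test_always_positive_definite(self, model, d):
        for seed in range(5):
            Om = gen_precision(PrecisionModelSpec(model=model, d=d, seed=seed))
            assert np.all(np.linalg.eigvalsh(Om) > 0)
            np.testing.assert_allclose(Om, Om.T)

    def test_hub_edge_frequencies(self):
        d, reps = 99, 120
        hub_hits, hub_tot, off_hits, off_tot = 0, 0, 0, 0
        for seed in range(reps):
            spec = PrecisionModelSpec(model="hub", d=d, seed=seed)
            Om = gen_precision(spec)
            # recover hub identity: hubs have the largest degree
            adj = (Om != 0) & ~np.eye(d, dtype=bool)
            deg = adj.sum(axis=1)
            hubs = np.argsort(-deg)[:3]
            is_hub = np.zeros(d, dtype=bool)
            is_hub[hubs] = True
            iu = np.triu_indices(d, 1)
            hub_pair = is_hub[iu[0]] | is_hub[iu[1]]
            hub_hits += adj[iu][hub_pair].sum()
            hub_tot += hub_pair.sum()
            off_hits += adj[iu][~hub_pair].sum()
            off_tot += (~hub_pair).sum()
        for hits, tot, p in ((hub_hits, hub_tot, 0.7), (off_hits, off_tot, 0.2)):
            se = np.sqrt(p * (1 - p) / tot)
            assert abs(hits / tot - p) < 4 * se

    def test_block_edge_frequencies(self):
        d, reps = 100, 60
        win_h = win_t = btw_h = btw_t = 0
        block = np.floor(np.arange(d) * 10 / d).astype(int)
        iu = np.triu_indices(d, 1)
        same = block[iu[0]] == block[iu[1]]
        for seed in range(reps):
            Om = gen_precision(PrecisionModelSpec(model="block", d=d, seed=seed))
            adj = (Om != 0) & ~np.eye(d, dtype=bool)
            win_h += adj[iu][same].sum()
            win_t += same.sum()
            btw_h += adj[iu][~same].sum()
            btw_t += (~same).sum()
        for hits, tot, p in ((win_h, win_t, 0.5), (btw_h, btw_t, 0.2)):
            se = np.sqrt(p * (1 - p) / tot)
            assert abs(hits / tot - p) < 4 * se

    def test_hub_block_magnitudes(self):
        Om = gen_precision(PrecisionModelSpec(model="block", d=30, seed=0))
        off = Om[np.triu_indices(30, 1)]
        vals = np.unique(np.abs(off[off != 0]))
        np.testing.assert_allclose(vals, [0.3])

    def test_sparse_identity_tail(self):
        d = 49
        spec = PrecisionModelSpec(model="sparse", d=d, seed=1)
        Om = gen_precision(spec)
        p1 = int(np.floor(3 * np.sqrt(d)))
        tail = Om[p1:, p1:]
        np.testing.assert_allclose(tail, np.eye(d - p1))
        assert not Om[p1:, :p1].any()


class TestLnSimulation:
    def test_seed_determinism(self):
        tree = random_binary_tree(12, seed=1)
        Om = gen_precision(PrecisionModelSpec(model="hub", d=tree.d, seed=2))
        a = simulate_ln_dataset(tree, Om, n=15, total=2000, seed=3)
        b = simulate_ln_dataset(tree, Om, n=15, total=2000, seed=3)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.m, b.m)

    def test_identity_precision_recovers_identity_balance_cov(self):
        """With Omega0 = I and m = 0 the ilr balances of the empirical
        compositions have near-identity covariance at large depth."""
        tree = balanced_tree(8)
        ds = simulate_ln_dataset(tree, np.eye(tree.d), n=600, total=1_000_000,
                                 seed=4, mean_sd=0.0)
        phat = ds.X / ds.X.sum(axis=1, keepdims=True)
        eta_hat = ilr_forward(np.maximum(phat, 1e-12), tree)
        cov = np.cov(eta_hat, rowvar=False)
        assert np.abs(cov - np.eye(tree.d)).max() < 0.25

    def test_true_clr_corr_is_exact_linear_map(self):
        tree = random_binary_tree(10, seed=5)
        Om = gen_precision(PrecisionModelSpec(model="block", d=tree.d, seed=6))
        corr = true_clr_corr_from_ilr(Om, tree)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)
        # Monte-Carlo cross-check of the closed form
        rng = np.random.default_rng(7)
        eta = rng.multivariate_normal(np.zeros(tree.d), np.linalg.inv(Om), 40_000)
        z = eta @ tree.ilr_basis()
        mc = np.corrcoef(z, rowvar=False)
        assert np.abs(mc - corr).max() < 0.05


class TestDtm:
    def test_branch_mean_recovery(self):
        tree = balanced_tree(8)
        mu = np.linspace(0.2, 0.8, tree.d)
        dtm = DTMParams(mu_A=mu, nu_A=np.full(tree.d, 5.0))
        X = simulate_dtm_dataset(tree, dtm, n=2000, total=5000, seed=8)
        nct = aggregate_node_counts(X, tree)
        theta_hat = nct.y_left.sum(axis=0) / nct.y.sum(axis=0)
        sd = np.sqrt(mu * (1 - mu) / (5.0 + 1)) / np.sqrt(2000)
        assert np.all(np.abs(theta_hat - mu) < 5 * np.maximum(sd, 1e-3))

    def test_concentration_limit_is_uniform(self):
        tree = balanced_tree(8)
        dtm = DTMParams(mu_A=np.full(tree.d, 0.5), nu_A=np.full(tree.d, 1e6))
        X = simulate_dtm_dataset(tree, dtm, n=30, total=1_000_000, seed=9)
        phat = X / X.sum(axis=1, keepdims=True)
        assert np.abs(phat - 1.0 / 8).max() < 0.01

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DTMParams(mu_A=np.array([1.2]), nu_A=np.array([1.0]))
        with pytest.raises(ValueError):
            DTMParams(mu_A=np.array([0.5]), nu_A=np.array([0.0]))


class TestInjectSignal:
    def test_zero_effect_is_identity(self, rng):
        X = rng.integers(0, 50, size=(10, 6))
        groups = np.arange(10) % 2
        out, chosen = inject_signal(X, groups, 2, 0.0, seed=10)
        np.testing.assert_array_equal(out, X)

    def test_rounding_rule(self):
        X = np.full((2, 3), 10)
        out, chosen = inject_signal(X, np.array([0, 1]), 3, 0.5,
                                    candidate_taxa=[0, 1, 2], seed=11)
        np.testing.assert_array_equal(out[1], 15)
        np.testing.assert_array_equal(out[0], 10)

    def test_group_zero_untouched_and_candidates_by_abundance(self, rng):
        X = rng.integers(0, 200, size=(30, 25))
        groups = rng.permutation(np.arange(30) % 2)
        out, chosen = inject_signal(X, groups, 8, 1.0, seed=12)
        np.testing.assert_array_equal(out[groups == 0], X[groups == 0])
        rel = X / X.sum(axis=1, keepdims=True)
        top20 = set(np.argsort(-rel.mean(axis=0))[:20])
        assert set(chosen) <= top20
        assert chosen.size == 8

    def test_table_grid_runs(self, rng):
        X = rng.integers(0, 100, size=(12, 30))
        groups = np.arange(12) % 2
        for k_star, a_star in [(1, 0.5), (1, 2), (1, 4), (8, 0.5), (8, 0.75), (8, 1)]:
            out, chosen = inject_signal(X, groups, k_star, a_star, seed=13)
            assert chosen.size == k_star

    def test_node_effects_zero_off_ancestors(self):
        tree = random_binary_tree(12, seed=14)
        p0 = np.full(12, 1 / 12)
        eff = injection_node_effects(tree, p0, np.array([3]), 2.0)
        on_path = tree.node_mask[:, 3]
        assert np.all(eff[~on_path] == 0.0)
        assert np.all(eff[on_path] != 0.0)


class TestLossesAndZeros:
    def test_identical_matrices_zero_loss(self, rng):
        A = rng.normal(size=(5, 5))
        A = A + A.T
        rep = loss_suite(A, A)
        assert rep.frobenius == rep.l1 == rep.linf == rep.spectral == 0.0

    def test_hand_losses(self):
        est = np.array([[1.0, 0.3], [0.3, 1.0]])
        true = np.eye(2)
        rep = loss_suite(est, true)
        assert rep.frobenius == pytest.approx(np.sqrt(2 * 0.09), abs=1e-12)
        assert rep.l1 == pytest.approx(0.3)
        assert rep.linf == pytest.approx(0.3)
        assert rep.spectral == pytest.approx(0.3)

    def test_symmetry_in_arguments(self, rng):
        A = rng.normal(size=(4, 4))
        B = rng.normal(size=(4, 4))
        assert loss_suite(A, B).as_dict() == loss_suite(B, A).as_dict()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_suite(np.eye(2), np.eye(3))

    def test_zero_proportions_counting(self):
        oz, sz = zero_proportion_stats(np.array([[0, 1], [2, 0]]))
        np.testing.assert_allclose(oz, [0.5, 0.5])
        np.testing.assert_allclose(sz, [0.5, 0.5])
        ozf, szf = zero_proportion_stats(np.ones((3, 4), dtype=int))
        assert not ozf.any() and not szf.any()

    def test_ks_bounds(self, rng):
        a = rng.random(40)
        assert ks_distance(a, a) == 0.0
        b = rng.random(40) + 10
        assert ks_distance(a, b) == 1.0


class TestSparsitySweep:
    def test_monotone_zero_response(self):
        tree = random_binary_tree(24, seed=15)
        rng = np.random.default_rng(16)
        mu = rng.normal(0, 1.0, tree.d)
        Sigma = np.eye(tree.d)
        totals = np.full(120, 3000)
        recs = sparsity_sweep(mu, Sigma, mean_scales=[0.25, 1.0, 4.0],
                              var_scales=[0.25, 1.0, 4.0, 16.0], tree=tree,
                              totals=totals, seed=17)
        var_med = [np.median(r["sample_zero"]) for r in recs if r["kind"] == "variance"]
        mean_med = [np.median(r["otu_zero"]) for r in recs if r["kind"] == "mean"]
        assert var_med == sorted(var_med)
        assert mean_med == sorted(mean_med)


class TestCohort:
    def test_shapes_and_determinism(self):
        tree = random_binary_tree(20, seed=18)
        X1, g1, t1, _ = simulate_da_cohort(tree, G=5, per_subject=4, seed=19)
        X2, g2, t2, _ = simulate_da_cohort(tree, G=5, per_subject=4, seed=19)
        np.testing.assert_array_equal(X1, X2)
        assert X1.shape == (20, 20)
        np.testing.assert_array_equal(g1, np.repeat(np.arange(5), 4))
        np.testing.assert_array_equal(X1.sum(axis=1), t1)

    def test_subject_effects_induce_within_subject_correlation(self):
        tree = random_binary_tree(10, seed=20)
        X, g, totals, psi = simulate_da_cohort(tree, G=40, per_subject=2,
                                               sd_re=1.5, sd_eps=0.3, seed=21)
        # pairs from the same subject are closer in log-odds space
        a, b = psi[::2], psi[1::2]
        within = np.linalg.norm(a - b, axis=1).mean()
        between = np.linalg.norm(a - np.roll(b, 1, axis=0), axis=1).mean()
        assert within < between
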