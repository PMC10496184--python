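"""EM engine: closed-form sub-update oracles, recovery, and fit contracts."""

import numpy as np
import pytest

from zinbmm.core_model import BatchDesign, CountMatrix, ZinbmmParams, nb_logpmf
from zinbmm.em_engine import (
    _cluster_weights,
    _FastData,
    _m_table,
    _optimize_phi_stats,
    _suff_stats,
    _update_gamma_stats,
    e_step,
    fit,
    fit_global,
    fit_global_gene,
    initialize,
    selected_genes,
    update_gamma,
    update_m,
    update_p,
    update_phi,
    update_pi,
)
from zinbmm.penalized_beta import solve_beta_stats

from conftest import two_cluster_counts


def zinb_sample(rng, n, pi, mu, phi):
    lam = rng.gamma(shape=phi, scale=mu / phi, size=n)
    x = rng.poisson(lam)
    x[rng.random(n) < pi] = 0
    return x


class TestGlobalFit:
    def test_gene_without_zeros_has_no_dropout(self, rng):
        x = rng.poisson(20, size=80) + 1
        B = BatchDesign(np.ones((80, 1)))
        _, pi_t, _, _ = fit_global_gene(x, B)
        assert pi_t <= 1e-3

    def test_constant_counts_recover_mean(self):
        x = np.full(60, 7)
        B = BatchDesign(np.ones((60, 1)))
        beta_t, _, phi_t, gamma_t = fit_global_gene(x, B)
        assert np.exp(beta_t) == pytest.approx(7.0, rel=0.01)
        assert phi_t > 50  # no overdispersion in constant data
        assert gamma_t[0] == 0.0

    def test_all_zero_gene_degenerate_fallback(self):
        x = np.zeros(40, dtype=int)
        B = BatchDesign(np.ones((40, 1)))
        beta_t, pi_t, phi_t, _ = fit_global_gene(x, B)
        assert pi_t == pytest.approx(0.99)
        assert beta_t == pytest.approx(np.log(0.01))
        assert phi_t == pytest.approx(10.0)

    def test_parameter_recovery_zinb(self, rng):
        """Many iid replicate genes at (pi=0.4, mu=8, phi=2): median recovered
        parameters land near the truth."""
        n, reps = 50, 200
        x = np.column_stack([zinb_sample(rng, n, 0.4, 8.0, 2.0)
                             for _ in range(reps)])
        gf = fit_global(CountMatrix(x), BatchDesign(np.ones((n, 1))))
        assert np.median(gf.pi_tilde) == pytest.approx(0.4, abs=0.08)
        assert np.median(np.exp(gf.beta_star)) == pytest.approx(8.0, rel=0.15)
        assert np.median(gf.phi_tilde) == pytest.approx(2.0, abs=0.8)

    def test_batch_coefficient_recovery(self, rng):
        """Per-gene global fits recover a known batch contrast."""
        n = 400
        B = BatchDesign.from_labels(["a"] * 200 + ["b"] * 200)
        offset = np.where(np.arange(n) < 200, 0.0, 0.6)
        x = np.column_stack([
            rng.poisson(rng.gamma(3.0, np.exp(1.0 + offset) / 3.0))
            for _ in range(50)]).reshape(n, 50)
        gf = fit_global(CountMatrix(x), B)
        assert np.median(gf.gamma_tilde[:, 1]) == pytest.approx(0.6, abs=0.1)


class TestInitialize:
    def test_single_cluster_uses_global_mean(self, toy_counts, toy_batches):
        params, gf = initialize(toy_counts, toy_batches, 1)
        np.testing.assert_array_equal(params.beta[:, 0], gf.beta_star)

    def test_staggering_arithmetic(self, toy_counts, toy_batches):
        params, gf = initialize(toy_counts, toy_batches, 3)
        for k in range(3):
            np.testing.assert_allclose(params.beta[:, k],
                                       gf.beta_star * (1 + 0.01 * k), rtol=1e-14)
        np.testing.assert_allclose(params.p, [1 / 3] * 3)

    def test_pi_clipped_at_ceiling(self, toy_counts, toy_batches):
        _, gf = initialize(toy_counts, toy_batches, 1)
        gf.pi_tilde[:] = 0.999
        params, _ = initialize(toy_counts, toy_batches, 3, gf)
        assert params.pi.max() <= 0.999

    def test_too_many_clusters_rejected(self, toy_counts, toy_batches):
        with pytest.raises(ValueError):
            initialize(toy_counts, toy_batches, 99)


class TestEStep:
    def test_identical_clusters_give_uniform_posterior(self, toy_counts,
                                                       toy_batches, toy_params):
        params = toy_params.copy()
        params.pi[:, 1] = params.pi[:, 0]
        params.beta[:, 1] = params.beta[:, 0]
        params.p = np.array([0.5, 0.5])
        z = e_step(toy_counts, toy_batches, params)
        np.testing.assert_allclose(z, 0.5, atol=1e-12)

    def test_single_cluster_posterior_is_one(self, toy_counts, toy_batches,
                                             toy_params):
        params = ZinbmmParams(np.array([1.0]), toy_params.pi[:, :1],
                              toy_params.beta[:, :1], toy_params.phi,
                              toy_params.gamma, toy_params.beta_star)
        z = e_step(toy_counts, toy_batches, params)
        np.testing.assert_allclose(z, 1.0)

    def test_matches_direct_bayes_rule(self, rng):
        """4-cell x 2-gene toy against an explicit probability-space oracle."""
        import scipy.stats as st
        X = CountMatrix(np.array([[0, 3], [5, 0], [2, 2], [0, 0]]))
        B = BatchDesign(np.ones((4, 1)))
        params = ZinbmmParams(
            p=np.array([0.3, 0.7]), pi=rng.uniform(0.1, 0.5, (2, 2)),
            beta=rng.normal(1, 0.4, (2, 2)), phi=rng.uniform(1, 4, 2),
            gamma=np.zeros(1), beta_star=np.zeros(2))
        z = e_step(X, B, params)
        for i in range(4):
            lik = np.empty(2)
            for k in range(2):
                mu = np.exp(params.beta[:, k])
                nb = st.nbinom.pmf(X.values[i], params.phi,
                                   params.phi / (mu + params.phi))
                f = params.pi[:, k] * (X.values[i] == 0) + (1 - params.pi[:, k]) * nb
                lik[k] = params.p[k] * np.prod(f)
            np.testing.assert_allclose(z[i], lik / lik.sum(), atol=1e-12)


class TestMStepUpdates:
    def test_update_p(self):
        z = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        np.testing.assert_array_equal(update_p(z), [1.0, 0.0])
        z2 = np.array([[0.2, 0.8], [0.6, 0.4], [0.7, 0.3]])
        np.testing.assert_allclose(update_p(z2), [0.5, 0.5])

    def test_update_m_scalar_formula(self, toy_batches):
        """(pi=0.3, mu=5, phi=2, x=0) -> 0.3 / (0.3 + 0.7*(2/7)^2)."""
        X = CountMatrix(np.array([[0], [3], [0], [1], [2]]))
        params = ZinbmmParams(np.array([1.0]), np.array([[0.3]]),
                              np.array([[np.log(5.0)]]), np.array([2.0]),
                              np.zeros(2), np.array([0.0]))
        m = update_m(X, toy_batches, params)
        expected = 0.3 / (0.3 + 0.7 * (2 / 7) ** 2)
        assert m[0, 0, 0] == pytest.approx(expected, rel=1e-12)
        assert m[1, 0, 0] == 0.0  # positive count can never be a dropout
        assert m[2, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_update_m_pure_dropout(self, toy_batches):
        X = CountMatrix(np.zeros((5, 1), dtype=int))
        params = ZinbmmParams(np.array([1.0]), np.array([[1.0]]),
                              np.array([[1.0]]), np.array([2.0]),
                              np.zeros(2), np.array([0.0]))
        m = update_m(X, toy_batches, params)
        np.testing.assert_allclose(m[:, 0, 0], 1.0)

    def test_update_pi_hand_ratio(self):
        z = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        m = np.zeros((3, 1, 2))
        m[:, 0, 0] = [1.0, 0.0, 1.0]
        m[:, 0, 1] = [0.5, 0.0, 0.0]
        pi = update_pi(z, m)
        assert pi[0, 0] == pytest.approx((0.9 + 0.2) / 1.6, rel=1e-12)
        assert pi[0, 1] == pytest.approx(0.05 / 1.4, rel=1e-12)

    def test_update_pi_bounds_and_empty_guard(self):
        z = np.array([[1.0, 0.0], [1.0, 0.0]])
        m = np.zeros((2, 1, 2))
        prev = np.array([[0.42, 0.37]])
        pi = update_pi(z, m, prev)
        assert pi[0, 0] <= 1e-5          # no dropout mass -> pi at the floor
        assert pi[0, 1] == pytest.approx(0.37)  # empty cluster frozen

    def test_update_phi_matches_grid_search(self, rng):
        """Single-cluster, no-dropout weighted MLE vs a 1-D grid oracle."""
        n = 120
        x = rng.negative_binomial(3, 3 / (3 + 9), size=(n, 1))
        X = CountMatrix(x)
        B = BatchDesign(np.ones((n, 1)))
        beta_hat = np.log(x.mean())
        params = ZinbmmParams(np.array([1.0]), np.array([[1e-6]]),
                              np.array([[beta_hat]]), np.array([1.0]),
                              np.zeros(1), np.array([beta_hat]))
        z = np.ones((n, 1))
        m = np.zeros((n, 1, 1))
        phi = update_phi(X, B, params, z, m)
        for _ in range(6):  # a few warm-started rounds reach the optimum
            params = ZinbmmParams(params.p, params.pi, params.beta, phi,
                                  params.gamma, params.beta_star)
            phi = update_phi(X, B, params, z, m)
        grid = np.exp(np.linspace(np.log(0.2), np.log(50), 4000))
        lls = [nb_logpmf(x[:, 0], np.exp(beta_hat), g).sum() for g in grid]
        assert np.log(phi[0]) == pytest.approx(
            np.log(grid[int(np.argmax(lls))]), abs=0.02)

    def test_update_phi_poisson_like_gene(self, rng):
        x = rng.poisson(6.0, size=(200, 1))
        X = CountMatrix(x)
        B = BatchDesign(np.ones((200, 1)))
        params = ZinbmmParams(np.array([1.0]), np.array([[1e-6]]),
                              np.array([[np.log(x.mean())]]), np.array([5.0]),
                              np.zeros(1), np.array([0.0]))
        z = np.ones((200, 1))
        m = np.zeros((200, 1, 1))
        phi = params.phi
        for _ in range(8):
            params = ZinbmmParams(params.p, params.pi, params.beta, phi,
                                  params.gamma, params.beta_star)
            phi = update_phi(X, B, params, z, m)
        assert phi[0] > 50

    def test_phi_sampling_distribution(self, rng):
        """NB genes (mu=10, phi=2, n=500): phi-hat concentrates near 2."""
        n, reps = 500, 100
        x = rng.poisson(rng.gamma(2.0, 10.0 / 2.0, size=(n, reps)))
        X = CountMatrix(x)
        B = BatchDesign(np.ones((n, 1)))
        beta_hat = np.log(x.mean(axis=0))
        params = ZinbmmParams(np.array([1.0]), np.full((reps, 1), 1e-6),
                              beta_hat[:, None], np.full(reps, 1.0),
                              np.zeros(1), beta_hat)
        z = np.ones((n, 1))
        m = np.zeros((n, reps, 1))
        phi = params.phi
        for _ in range(8):
            params = ZinbmmParams(params.p, params.pi, params.beta, phi,
                                  params.gamma, params.beta_star)
            phi = update_phi(X, B, params, z, m)
        inside = np.mean((phi > 1.5) & (phi < 2.7))
        assert inside >= 0.9

    def test_update_gamma_single_batch_fixed(self, toy_counts, toy_params):
        B = BatchDesign(np.ones((5, 1)))
        params = toy_params.copy()
        params.gamma = np.array([0.0])
        z = np.full((5, 2), 0.5)
        m = np.zeros((5, 3, 2))
        gamma = update_gamma(toy_counts, B, params, z, m)
        assert gamma[0] == 0.0

    def test_update_gamma_doubling_scaling_oracle(self, rng):
        """Doubling batch-2 counts raises the batch contrast by ~log 2."""
        n = 300
        B = BatchDesign.from_labels(["a"] * 150 + ["b"] * 150)
        mu = rng.uniform(3, 15, size=40)
        x = rng.poisson(rng.gamma(3.0, mu[None, :] / 3.0, size=(n, 40))).astype(np.int64)
        X1 = CountMatrix(x)
        x2 = x.copy()
        x2[150:] *= 2
        X2 = CountMatrix(x2)
        beta = np.log(x[:150].mean(axis=0) + 0.5)
        params = ZinbmmParams(np.array([1.0]), np.full((40, 1), 1e-6),
                              beta[:, None], np.full(40, 3.0),
                              np.zeros(2), beta)
        z = np.ones((n, 1))
        m = np.zeros((n, 40, 1))
        g1 = update_gamma(X1, B, params, z, m)
        g2 = update_gamma(X2, B, params, z, m)
        assert g2[1] - g1[1] == pytest.approx(np.log(2), abs=0.05)


class TestFit:
    def test_total_shrinkage_under_huge_penalty(self):
        X, B, _ = two_cluster_counts(n=40, J=15, seed=1)
        res = fit(X, B, 2, lam=1e5, max_iter=30)
        assert res.selected_genes == []
        np.testing.assert_array_equal(res.params.beta,
                                      np.repeat(res.params.beta_star[:, None],
                                                2, axis=1))

    def test_single_cluster_fit(self):
        X, B, _ = two_cluster_counts(n=30, J=10, seed=2)
        res = fit(X, B, 1, lam=1.0)
        assert set(res.labels) == {0}
        np.testing.assert_allclose(res.params.beta[:, 0], res.params.beta_star)
        assert res.selected_genes == []

    def test_determinism(self):
        X, B, _ = two_cluster_counts(n=50, J=20, seed=3)
        a = fit(X, B, 2, lam=0.5, seed=7)
        b = fit(X, B, 2, lam=0.5, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.selected_genes == b.selected_genes
        np.testing.assert_array_equal(a.params.beta, b.params.beta)

    def test_recovers_well_separated_clusters(self):
        from zinbmm.metrics import ari
        hits = 0
        for seed in range(6):
            X, B, truth = two_cluster_counts(n=200, J=100, delta=1.6,
                                             seed=seed, pi_drop=0.1)
            res = fit(X, B, 2, lam=2.0)
            hits += ari(truth, res.labels) == 1.0
        assert hits >= 5

    def test_label_permutation_equivalence(self):
        """Fits started from permuted cluster orderings agree with truth
        equally well."""
        from zinbmm.metrics import ari
        X, B, truth = two_cluster_counts(n=120, J=60, delta=1.6, seed=4)
        params, gf = initialize(X, B, 2)
        res = fit(X, B, 2, lam=1.0, init=params, global_fit=gf)
        perm = params.copy()
        perm.p = params.p[::-1].copy()
        perm.pi = params.pi[:, ::-1].copy()
        perm.beta = params.beta[:, ::-1].copy()
        res_p = fit(X, B, 2, lam=1.0, init=perm, global_fit=gf)
        assert ari(truth, res.labels) == pytest.approx(
            ari(truth, res_p.labels), abs=1e-12)

    def test_overfitted_k_stays_finite(self):
        """K above the true cluster count never produces NaN/Inf params."""
        X, B, _ = two_cluster_counts(n=60, J=20, seed=5)
        res = fit(X, B, 4, lam=1.0, max_iter=40)
        res.params.validate()
        z = res.resp.z_hat
        np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-10)

    def test_objective_trace_is_nondecreasing(self):
        for seed in range(4):
            X, B, _ = two_cluster_counts(n=50, J=25, seed=seed)
            res = fit(X, B, 2, lam=1.0, max_iter=40)
            diffs = np.diff(res.objective_trace)
            assert np.all(diffs > -1e-4)

    def test_m_hat_zero_on_positive_counts(self):
        X, B, _ = two_cluster_counts(n=40, J=12, seed=6)
        res = fit(X, B, 2, lam=1.0, max_iter=15)
        positive = X.values > 0
        assert np.all(res.resp.m_hat[positive] == 0)

    def test_dropout_probability_recovery_main_design(self):
        """Median |pi_hat - pi| over informative genes stays below 0.1 on
        medium-dropout main-design data (clusters aligned by best
        permutation)."""
        import itertools

        from zinbmm.simulate import SimulationConfig, simulate_main
        errs = []
        for seed in (1, 2):
            cfg = SimulationConfig(n=300, J=1000, K=3, dropout_level="medium",
                                   gamma=(0.1, 0.2), Delta=1.2, seed=seed)
            t = simulate_main(cfg)
            res = fit(t.X, t.B, 3, lam=2.23, max_iter=80)
            best = max(
                itertools.permutations(range(3)),
                key=lambda p: np.mean(np.array(p)[t.labels - 1] == res.labels))
            est = res.params.pi[:, list(best)]
            errs.append(np.median(
                np.abs(est - t.gen_params["pi"])[t.informative]))
        assert max(errs) < 0.1

    def test_selected_genes_helper(self):
        X, B, _ = two_cluster_counts(n=40, J=15, seed=7)
        res = fit(X, B, 2, lam=0.1, max_iter=20)
        assert selected_genes(res) == res.selected_genes
        assert set(res.selected_genes) <= set(X.gene_ids)


class TestFastPathEquivalence:
    """The batch-collapsed statistics used inside `fit` reproduce the direct
    dense sub-updates."""

    def test_one_m_step_matches_dense(self, rng):
        from zinbmm.simulate import SimulationConfig, simulate_main
        t = simulate_main(SimulationConfig(n=50, J=30, K=3, seed=11,
                                           frac_informative=0.2))
        params, gf = initialize(t.X, t.B, 3)
        z = e_step(t.X, t.B, params)
        m = update_m(t.X, t.B, params, z)
        data = _FastData(t.X, t.B)
        m_t, A, W, Sx = _suff_stats(data, params, z)
        # dropout table expands to the dense posterior
        batch = t.B.batch_index()
        for i in (0, 25, 49):
            for j in (0, 7):
                for k in range(3):
                    expected = m_t[batch[i], j, k] if t.X.values[i, j] == 0 else 0.0
                    assert m[i, j, k] == pytest.approx(expected, rel=1e-12)
        # pi update from the aggregated statistics
        pi_dense = update_pi(z, m, params.pi)
        pi_fast = np.clip(A.sum(axis=0) / z.sum(axis=0)[None, :], 1e-6, 1 - 1e-6)
        np.testing.assert_allclose(pi_dense, pi_fast, atol=1e-12)
        # gamma update
        phi_new = update_phi(t.X, t.B, params, z, m)
        g_dense = update_gamma(t.X, t.B, params, z, m, phi_new)
        g_fast = _update_gamma_stats(W, Sx, params.beta, phi_new, params.gamma)
        np.testing.assert_allclose(g_dense, g_fast, atol=1e-6)
        # beta update
        from zinbmm.em_engine import update_beta
        b_dense = update_beta(t.X, t.B, params, z, m, 1.5, phi_new, g_dense)
        for k in range(3):
            b_fast = solve_beta_stats(W[:, :, k], Sx[:, :, k], g_dense,
                                      phi_new, 1.5, params.beta_star,
                                      params.beta[:, k])
            np.testing.assert_allclose(b_dense[:, k], b_fast, atol=1e-10)
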