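"""Kinship construction and mixed-model likelihood machinery."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from epiqtl.lmm import (
    EmptyCisWindowError,
    KinshipMatrix,
    compute_kinship,
    compute_local_kinship,
    fit_mixed_model,
    likelihood_ratio_test,
)
from epiqtl.lmm import _fit_multi_kinship, _fit_one_kinship_spectral

from conftest import make_full_rank_kinship


class TestComputeKinship:
    def test_single_variant_outer_product_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(1, 12))
        K = compute_kinship(v).matrix
        z = (v[0] - v[0].mean()) / v[0].std()
        expected = np.outer(z, z)
        expected /= np.diag(expected).mean()
        np.testing.assert_allclose(K, expected, atol=1e-10)
        assert np.linalg.matrix_rank(K, tol=1e-8) == 1

    def test_identical_accessions_share_diagonal_value(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(60, 10)).astype(float)
        X[:, 1] = X[:, 0]  # accession 1 duplicates accession 0
        K = compute_kinship(X).matrix
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_spectral_reconstruction(self, small_K):
        w, Q = np.linalg.eigh(small_K.matrix)
        np.testing.assert_allclose(Q @ np.diag(w) @ Q.T, small_K.matrix, atol=1e-10)

    def test_constant_rows_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_kinship(np.ones((5, 8)))

    def test_non_psd_matrix_rejected(self):
        M = np.eye(4)
        M[0, 0] = -1.0
        with pytest.raises(ValueError):
            KinshipMatrix(role="global_snp", matrix=M)


class TestLocalKinship:
    def test_window_covering_all_snps_equals_global(self, small_panel, small_K):
        gene = {"gene_id": "g", "chrom": "1", "start": 0,
                "end": int(small_panel.pos[-1]) + 1}
        K_l = compute_local_kinship(small_panel, gene, window_bp=10**9)
        np.testing.assert_allclose(K_l.matrix, small_K.matrix, atol=1e-10)

    def test_empty_window_raises_fallback_signal(self, small_panel):
        gene = {"gene_id": "g", "chrom": "99", "start": 0, "end": 100}
        with pytest.raises(EmptyCisWindowError):
            compute_local_kinship(small_panel, gene, window_bp=1000)

    def test_cis_variance_captured_by_local_component(self, panel, K_S):
        # trait driven by one cis SNP: sigma_l^2 should absorb its variance
        gene = {"gene_id": "g", "chrom": "1", "start": 995000, "end": 997000}
        K_l = compute_local_kinship(panel, gene, window_bp=20000)
        cis = np.flatnonzero((panel.pos >= 975000) & (panel.pos < 1017000))
        x = panel.matrix[:, cis[len(cis) // 2]].astype(float)
        x = (x - x.mean()) / x.std()
        fracs = []
        for rep in range(50):
            rng = np.random.default_rng(rep)
            y = np.sqrt(0.4) * x + np.sqrt(0.6) * rng.normal(size=len(x))
            fit = fit_mixed_model(y, kinships=(K_S, K_l))
            fracs.append(fit.genetic_fraction("local_cis"))
        assert np.mean(fracs) > 0.2  # recovers a substantial cis share


class TestFitMixedModel:
    def test_noiseless_fixed_effects(self, full_rank_kinship):
        rng = np.random.default_rng(2)
        n = 30
        K = full_rank_kinship(n, seed=7)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_true = np.array([1.5, -2.0])
        y = X @ beta_true
        fit = fit_mixed_model(y, X, kinships=(K,))
        vy = np.var(y)
        assert fit.variance_components["residual"] <= 1e-8 * vy
        assert fit.variance_components["global_snp"] <= 1e-8 * vy
        np.testing.assert_allclose(fit.beta, beta_true, atol=1e-6)

    @pytest.mark.parametrize("n_kinships", [1, 2])
    def test_loglik_matches_dense_mvn_oracle(self, n_kinships, full_rank_kinship):
        # brute-force check: the reported ML log-likelihood equals the exact
        # multivariate-normal density at the fitted parameters
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 40
            Ks = tuple(
                full_rank_kinship(n, seed=10 + seed + j,
                                  role=f"k{j}") for j in range(n_kinships)
            )
            cov = 0.5 * Ks[0].matrix + 0.5 * np.eye(n)
            y = rng.multivariate_normal(np.zeros(n), cov)
            fit = fit_mixed_model(y, kinships=Ks, criterion="ML")
            Sigma = fit.variance_components["residual"] * np.eye(n)
            for K in Ks:
                Sigma = Sigma + fit.variance_components[K.role] * K.matrix
            direct = multivariate_normal.logpdf(
                y, mean=np.full(n, fit.beta[0]), cov=Sigma
            )
            assert fit.log_likelihood == pytest.approx(direct, abs=1e-6)

    def test_heritability_recovery(self, K_S):
        fracs = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            y = rng.multivariate_normal(
                np.zeros(135), 0.5 * K_S.matrix + 0.5 * np.eye(135)
            )
            fit = fit_mixed_model(y, kinships=(K_S,))
            fracs.append(fit.genetic_fraction("global_snp"))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.07)

    def test_spectral_and_generic_paths_agree(self, full_rank_kinship):
        rng = np.random.default_rng(5)
        n = 35
        K = full_rank_kinship(n, seed=3)
        y = rng.multivariate_normal(np.zeros(n), 0.4 * K.matrix + 0.6 * np.eye(n))
        X = np.ones((n, 1))
        ll_spec, *_ = _fit_one_kinship_spectral(y, X, K, "ML")
        ll_gen, *_ = _fit_multi_kinship(y, X, (K,), "ML")
        assert ll_spec == pytest.approx(ll_gen, abs=1e-6)

    def test_permutation_invariance(self, full_rank_kinship):
        rng = np.random.default_rng(6)
        n = 30
        K = full_rank_kinship(n, seed=4)
        y = rng.multivariate_normal(np.zeros(n), 0.5 * K.matrix + 0.5 * np.eye(n))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        fit = fit_mixed_model(y, X, kinships=(K,))
        perm = rng.permutation(n)
        Kp = KinshipMatrix(role="global_snp", matrix=K.matrix[np.ix_(perm, perm)])
        fit_p = fit_mixed_model(y[perm], X[perm], kinships=(Kp,))
        assert fit.log_likelihood == pytest.approx(fit_p.log_likelihood, abs=1e-6)
        np.testing.assert_allclose(fit.beta, fit_p.beta, atol=1e-5)

    def test_adding_component_never_decreases_loglik(self, small_K, small_panel):
        rng = np.random.default_rng(7)
        n = small_K.n
        K2 = make_full_rank_kinship(n, seed=8, role="methylation")
        y = rng.multivariate_normal(np.zeros(n), 0.5 * small_K.matrix + 0.5 * np.eye(n))
        f0 = fit_mixed_model(y, kinships=())
        f1 = fit_mixed_model(y, kinships=(small_K,))
        f2 = fit_mixed_model(y, kinships=(small_K, K2))
        assert f1.log_likelihood >= f0.log_likelihood - 1e-8
        assert f2.log_likelihood >= f1.log_likelihood - 1e-8

    def test_rank_deficient_design_rejected(self, small_K):
        n = small_K.n
        X = np.ones((n, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_mixed_model(np.arange(n, dtype=float), X, kinships=(small_K,))


class TestLikelihoodRatioTest:
    def _fits(self, seed=0, h2=0.0, n=135, K_S=None, K_M=None):
        rng = np.random.default_rng(seed)
        cov = (1 - h2) * np.eye(n) + 0.5 * K_S.matrix
        if h2 > 0:
            cov = cov + h2 * K_M.matrix
        y = rng.multivariate_normal(np.zeros(n), cov)
        full = fit_mixed_model(y, kinships=(K_S, K_M))
        null = fit_mixed_model(y, kinships=(K_S,))
        return full, null

    def test_identical_models_give_zero_statistic(self, small_K):
        rng = np.random.default_rng(1)
        y = rng.normal(size=small_K.n)
        f = fit_mixed_model(y, kinships=(small_K,))
        res = likelihood_ratio_test(f, f)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_statistic_nonnegative_and_p_valid(self, K_S, panel):
        from epiqtl.datatypes import BIN_META_COLUMNS
        from epiqtl.simulate import simulate_methylation_bins

        sim = simulate_methylation_bins(panel, n_bins=200, seed=3)
        acc = [c for c in sim.bins.columns if c not in BIN_META_COLUMNS]
        K_M = compute_kinship(sim.bins[acc].to_numpy(float), role="methylation")
        for seed in range(5):
            full, null = self._fits(seed=seed, K_S=K_S, K_M=K_M)
            res = likelihood_ratio_test(full, null)
            assert res.statistic >= 0.0
            assert 0.0 < res.p_value <= 1.0

    def test_swapped_arguments_detected(self, K_S, panel):
        from epiqtl.datatypes import BIN_META_COLUMNS
        from epiqtl.simulate import simulate_methylation_bins

        sim = simulate_methylation_bins(panel, n_bins=200, seed=3)
        acc = [c for c in sim.bins.columns if c not in BIN_META_COLUMNS]
        K_M = compute_kinship(sim.bins[acc].to_numpy(float), role="methylation")
        full, null = self._fits(seed=11, h2=0.4, K_S=K_S, K_M=K_M)
        with pytest.raises(ValueError):
            likelihood_ratio_test(null, full)
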