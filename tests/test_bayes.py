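"""Gibbs samplers against closed-form and REML oracles.

The strongest surface: at fixed variance components the samplers' posterior
means must match closed-form mixed-model solutions; with variances sampled,
posterior-mean heritabilities must track REML on the same data.
"""

import numpy as np
import pytest

from grainpred import (McmcSpec, OmicsMatrix, compute_kernel, fit_bayesc,
                       fit_bivariate_gblup, fit_kernel_blup, fit_mols,
                       heritability, predict)

from conftest import standardized_matrix
from oracles import closed_form_blup, reml_kernel_h2


def _kernel_data(rng, n=80, m=400, h2=0.5):
    """Phenotype with genetic values drawn exactly from N(0, K h2)."""
    W = standardized_matrix(rng, n, m)
    K = compute_kernel(W)
    L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
    u = np.sqrt(h2) * (L @ rng.standard_normal(n))
    y = 3.0 + u + np.sqrt(1 - h2) * rng.standard_normal(n)
    return W, K, u, y


class TestMols:
    def test_noiseless_single_effect_recovered(self):
        rng = np.random.default_rng(0)
        W = standardized_matrix(rng, 30, 5, kind="metabolite")
        y = 1.5 + 2.0 * W.values[:, 2]
        fit = fit_mols(y, W)
        a = fit.random_effect_means["a"]
        assert a[2] == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(np.delete(a, 2), 0, atol=1e-8)

    def test_orthogonal_design_matches_normal_equations(self):
        W = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        y = np.array([2.0, 0.0, 1.0, -1.0])
        fit = fit_mols(y, W)
        # X'X = 4I: a_j = w_j.y / 4
        assert fit.random_effect_means["a"] == pytest.approx(
            [W[:, 0] @ y / 4, W[:, 1] @ y / 4])
        assert fit.mu_mean == pytest.approx(y.mean())

    def test_constant_phenotype_gives_zero_effects(self):
        rng = np.random.default_rng(1)
        W = standardized_matrix(rng, 20, 3)
        fit = fit_mols(np.full(20, 7.0), W)
        assert np.allclose(fit.random_effect_means["a"], 0, atol=1e-10)
        assert fit.mu_mean == pytest.approx(7.0)

    def test_overparameterized_rejected(self):
        rng = np.random.default_rng(2)
        W = standardized_matrix(rng, 10, 20)
        with pytest.raises(ValueError, match="BayesC|kernel"):
            fit_mols(rng.standard_normal(10), W)


class TestKernelBlup:
    def test_fixed_variances_match_closed_form_blup(self):
        rng = np.random.default_rng(3)
        _, K, _, y = _kernel_data(rng, n=50)
        fit = fit_kernel_blup(y, [K], mcmc=McmcSpec(6000, 1000, 2, seed=4),
                              fixed_variances={"u_genomic": 1.0, "e": 1.0})
        u_hat = closed_form_blup(y, K.values, 1.0, 1.0)
        u_post = fit.random_effect_means["u_genomic"]
        assert np.corrcoef(u_hat, u_post)[0, 1] > 0.999
        mc_se = 3 * np.sqrt(1.0 / 3000)
        assert np.abs(u_hat - u_post).max() < 3 * mc_se

    def test_null_heritability_near_zero(self):
        """No genetic signal: posterior h2 collapses to the small residual
        mass the half-phenotypic-variance prior retains (REML gives ~0)."""
        rng = np.random.default_rng(5)
        W = standardized_matrix(rng, 300, 50)  # rank-deficient, identifiable
        K = compute_kernel(W)
        y = rng.standard_normal(300)
        fit = fit_kernel_blup(y, [K], mcmc=McmcSpec(4000, 1500, 4, seed=6))
        assert fit.heritabilities["h2_genomic"] < 0.15
        h2_reml, _, _ = reml_kernel_h2(y, K.values)
        assert h2_reml < 0.02

    def test_h2_tracks_reml_oracle(self):
        rng = np.random.default_rng(7)
        _, K, _, y = _kernel_data(rng, n=200, m=800, h2=0.5)
        fit = fit_kernel_blup(y, [K], mcmc=McmcSpec(4000, 1000, 4, seed=8))
        h2_reml, _, _ = reml_kernel_h2(y, K.values)
        assert fit.heritabilities["h2_genomic"] == pytest.approx(h2_reml, abs=0.07)

    def test_two_kernel_reduction_when_one_component_is_null(self):
        """With the metabolic kernel variance pinned at ~0, the two-kernel
        sampler's genomic effects match the single-kernel solution."""
        rng = np.random.default_rng(9)
        _, K, _, y = _kernel_data(rng, n=100, h2=0.5)
        M = compute_kernel(standardized_matrix(rng, 100, 40, "metabolite"))
        fixed = {"u_metabolic": 1e-8, "u_genomic": 1.0, "e": 1.0}
        double = fit_kernel_blup(y, [M, K], mcmc=McmcSpec(6000, 1000, 3, seed=10),
                                 fixed_variances=fixed)
        u_hat = closed_form_blup(y, K.values, 1.0, 1.0)
        u_post = double.random_effect_means["u_genomic"]
        assert np.corrcoef(u_hat, u_post)[0, 1] > 0.999
        assert np.abs(double.random_effect_means["u_metabolic"]).max() < 1e-3

    def test_seed_invariance_of_posterior_means(self):
        rng = np.random.default_rng(11)
        _, K, _, y = _kernel_data(rng, n=80)
        fits = [fit_kernel_blup(y, [K], mcmc=McmcSpec(4000, 1000, 2, seed=s))
                for s in (1, 2)]
        h = [f.heritabilities["h2_genomic"] for f in fits]
        sd = np.std(fits[0].samples["h2_genomic"]) / np.sqrt(500)  # ESS guess
        assert abs(h[0] - h[1]) < max(6 * sd, 0.03)

    def test_masked_prediction_matches_conditional_mean_oracle(self):
        rng = np.random.default_rng(12)
        n = 60
        _, K, _, y = _kernel_data(rng, n=n)
        mask = np.zeros(n, dtype=bool)
        mask[:12] = True
        fit = fit_kernel_blup(y, [K], mcmc=McmcSpec(8000, 2000, 2, seed=13),
                              fixed_variances={"u_genomic": 1.0, "e": 1.0},
                              missing_mask=mask)
        obs = ~mask
        mu = y[obs].mean()
        u_all = K.values[:, obs] @ np.linalg.solve(
            K.values[np.ix_(obs, obs)] + np.eye(obs.sum()), y[obs] - mu)
        pred = predict(fit, target_lines=K.line_ids[mask])
        assert np.corrcoef(pred, mu + u_all[mask])[0, 1] > 0.99


class TestBayesC:
    def test_pi_to_zero_matches_kernel_blup_predictions(self):
        rng = np.random.default_rng(14)
        n, m = 120, 180
        W = standardized_matrix(rng, n, m)
        beta = rng.standard_normal(m) * np.sqrt(0.5 / m)
        y = 1.0 + W.values @ beta + rng.standard_normal(n) * np.sqrt(0.5)
        fit_c = fit_bayesc(y, W, pi=1e-6, mcmc=McmcSpec(2400, 800, 3, seed=15))
        K = compute_kernel(W)
        fit_k = fit_kernel_blup(y, [K], mcmc=McmcSpec(4000, 1000, 2, seed=16))
        pred_c = predict(fit_c, W_target=W)
        pred_k = predict(fit_k)
        assert np.corrcoef(pred_c, pred_k)[0, 1] > 0.99

    def test_null_trait_inclusion_matches_prior(self):
        rng = np.random.default_rng(17)
        W = standardized_matrix(rng, 150, 200)
        y = rng.standard_normal(150)
        fit = fit_bayesc(y, W, pi=0.99, mcmc=McmcSpec(3000, 1000, 3, seed=18))
        assert fit.inclusion_probs.mean() == pytest.approx(0.01, abs=0.005)

    def test_qtl_enrichment_of_inclusion_probabilities(self):
        rng = np.random.default_rng(19)
        n, m, n_qtl = 250, 1000, 20
        W = standardized_matrix(rng, n, m)
        qtl = rng.choice(m, n_qtl, replace=False)
        beta = np.zeros(m)
        beta[qtl] = rng.standard_normal(n_qtl) * np.sqrt(0.5 / n_qtl)
        y = W.values @ beta + rng.standard_normal(n) * np.sqrt(0.5)
        fit = fit_bayesc(y, W, pi=0.99, mcmc=McmcSpec(1500, 500, 3, seed=20))
        bg = np.setdiff1d(np.arange(m), qtl)
        assert (fit.inclusion_probs[qtl].mean()
                >= 5 * fit.inclusion_probs[bg].mean())

    def test_invalid_pi_rejected(self):
        rng = np.random.default_rng(21)
        W = standardized_matrix(rng, 20, 5)
        with pytest.raises(ValueError):
            fit_bayesc(rng.standard_normal(20), W, pi=1.0)


class TestBivariate:
    def _bivariate_data(self, rng, n=200, m=600, rg=0.7, h2=0.5):
        W = standardized_matrix(rng, n, m)
        K = compute_kernel(W)
        from grainpred.bayes import _kernel_eigen
        Q, d = _kernel_eigen(K)
        Sg = h2 * np.array([[1.0, rg], [rg, 1.0]])
        L = np.linalg.cholesky(Sg + 1e-10 * np.eye(2))
        Ut = (np.sqrt(d)[:, None] * rng.standard_normal((len(d), 2))) @ L.T
        U = Q @ Ut
        Y = U + rng.standard_normal((n, 2)) * np.sqrt(1 - h2)
        return K, U, Y

    def test_diagonal_truth_reduces_to_univariate_marginals(self):
        rng = np.random.default_rng(22)
        K, _, Y = self._bivariate_data(rng, n=150, rg=0.0)
        biv = fit_bivariate_gblup(Y, K, mcmc=McmcSpec(3000, 1000, 3, seed=23))
        uni = fit_kernel_blup(Y[:, 0], [K], mcmc=McmcSpec(3000, 1000, 3, seed=24))
        assert biv.heritabilities["h2_trait1"] == pytest.approx(
            uni.heritabilities["h2_genomic"], abs=0.07)
        u_b = biv.random_effect_means["u"][:, 0]
        u_u = uni.random_effect_means["u_genomic"]
        assert np.corrcoef(u_b, u_u)[0, 1] > 0.95

    def test_genetic_correlation_recovery(self):
        rng = np.random.default_rng(25)
        K, _, Y = self._bivariate_data(rng, n=300, rg=0.7)
        fit = fit_bivariate_gblup(Y, K, mcmc=McmcSpec(3000, 1000, 3, seed=26))
        assert fit.variance_components["genetic_correlation"] == pytest.approx(
            0.7, abs=0.15)

    def test_missing_records_augmented_and_predicted(self):
        rng = np.random.default_rng(27)
        K, U, Y = self._bivariate_data(rng, n=200, rg=0.9)
        Ymask = Y.copy()
        test = np.arange(40)
        Ymask[test, 0] = np.nan  # auxiliary observed everywhere (Scenario 2)
        fit = fit_bivariate_gblup(Ymask, K, mcmc=McmcSpec(2400, 800, 3, seed=28))
        pred = predict(fit, target_lines=K.line_ids[test])
        r = np.corrcoef(pred, Y[test, 0])[0, 1]
        assert r > 0.4  # informative despite fully masked target trait

    def test_trait_without_records_rejected(self):
        rng = np.random.default_rng(29)
        K, _, Y = self._bivariate_data(rng, n=50)
        Y[:, 1] = np.nan
        with pytest.raises(ValueError):
            fit_bivariate_gblup(Y, K)


class TestPredictAndHeritability:
    def test_training_predictions_are_fitted_values(self):
        rng = np.random.default_rng(30)
        _, K, _, y = _kernel_data(rng, n=40)
        fit = fit_kernel_blup(y, [K], mcmc=McmcSpec(2000, 500, 2, seed=31))
        full = predict(fit)
        sub = predict(fit, target_lines=K.line_ids[:10])
        assert np.allclose(full[:10], sub)

    def test_bayesc_with_no_included_effects_predicts_mu(self):
        fit = __import__("grainpred").bayes.PosteriorFit(
            model="bayesc", mu_mean=2.5)
        fit.random_effect_means["a"] = np.zeros(4)
        pred = predict(fit, W_target=np.random.default_rng(32).standard_normal((6, 4)))
        assert np.allclose(pred, 2.5)

    def test_unknown_line_rejected(self):
        rng = np.random.default_rng(33)
        _, K, _, y = _kernel_data(rng, n=20)
        fit = fit_kernel_blup(y, [K], mcmc=McmcSpec(500, 100, 1, seed=34))
        with pytest.raises(KeyError):
            predict(fit, target_lines=["nope"])

    def test_heritability_half_when_variances_equal(self):
        fit = __import__("grainpred").bayes.PosteriorFit(
            model="kernel_blup", mu_mean=0.0)
        s = np.ones(100)
        fit.samples = {"u_genomic": s, "e": s, "h2_genomic": s * 0.5}
        fit.heritabilities = {"h2_genomic": float((s / (s + s)).mean())}
        assert heritability(fit)["h2_genomic"] == 0.5
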