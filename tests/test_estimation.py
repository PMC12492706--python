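"""Moment conditions, weighted fits, outlier masking, and the full pipeline."""
import numpy as np
import pytest

import unico
from unico.containers import FeatureParams, FitConfig, ProportionMatrix
from unico.estimation import (
    _gauge_fix,
    fit_means,
    fit_variances,
    mask_outliers,
    moment_conditions,
    update_weights,
)
from unico.evaluation import robust_correlation


CFG = FitConfig()


def _uniform_props(rng, n, k, conc=None):
    conc = np.ones(k) if conc is None else np.asarray(conc, float)
    return ProportionMatrix(rng.dirichlet(conc, size=n))


class TestMomentConditions:
    def test_zero_first_residual_at_the_model_mean(self):
        rng = np.random.default_rng(0)
        props = _uniform_props(rng, 30, 3)
        p = FeatureParams([1.0, 2.0, 3.0], np.eye(3), 0.1)
        x = props.values @ p.mu
        mc = moment_conditions(p, x, props)
        assert np.allclose(mc.first, 0.0, atol=1e-12)

    def test_second_residual_direct_substitution(self):
        rng = np.random.default_rng(1)
        props = _uniform_props(rng, 10, 2)
        p = FeatureParams([1.0, 1.0], np.zeros((2, 2)), 0.7)
        x = props.values @ p.mu + 0.2
        mc = moment_conditions(p, x, props)
        assert np.allclose(mc.second, 0.7 - 0.04, atol=1e-12)

    def test_both_residuals_center_on_zero_at_truth(self):
        # law of large numbers at the generating parameters
        rng = np.random.default_rng(2)
        n, k = 100_000, 3
        props = _uniform_props(rng, n, k, conc=[5, 3, 2])
        sigma = np.array([[1.0, 0.3, 0.0], [0.3, 1.5, -0.2], [0.0, -0.2, 0.8]])
        p = FeatureParams([2.0, 4.0, 1.0], sigma, 0.3)
        L = np.linalg.cholesky(sigma)
        z = p.mu + rng.standard_normal((n, k)) @ L.T
        x = np.einsum("ih,ih->i", props.values, z) + rng.normal(0, np.sqrt(0.3), n)
        mc = moment_conditions(p, x, props)
        for resid in (mc.first, mc.second):
            se = resid.std(ddof=1) / np.sqrt(n)
            assert abs(resid.mean()) < 3 * se + 1e-12


class TestFitMeans:
    def test_exact_recovery_on_noiseless_data(self):
        rng = np.random.default_rng(3)
        props = _uniform_props(rng, 200, 2)
        mu = np.array([1.0, 3.0])
        x = props.values @ mu
        out, gamma, beta = fit_means(
            x, props, None, np.ones(200), np.ones(200, bool), CFG
        )
        assert np.abs(out - mu).max() < 1e-6
        assert gamma is None and beta is None

    def test_negative_truth_hits_the_boundary(self):
        rng = np.random.default_rng(4)
        props = _uniform_props(rng, 300, 2)
        x = props.values @ np.array([-1.0, 3.0])
        mu, *_ = fit_means(x, props, None, np.ones(300), np.ones(300, bool), CFG)
        assert mu[0] == pytest.approx(0.0, abs=1e-9)
        # boundary solution beats every feasible grid point
        def obj(m):
            return float(np.sum((x - props.values @ m) ** 2))
        best = obj(mu)
        for a in np.linspace(0, 2, 21):
            for b in np.linspace(0, 4, 41):
                assert best <= obj(np.array([a, b])) + 1e-9

    def test_all_zero_feature_gives_zero_params(self):
        rng = np.random.default_rng(5)
        props = _uniform_props(rng, 50, 3)
        mu, gamma, beta = fit_means(
            np.zeros(50), props, None, np.ones(50), np.ones(50, bool), CFG
        )
        assert np.allclose(mu, 0.0, atol=1e-12)

    def test_unweighted_unconstrained_equals_ols(self):
        rng = np.random.default_rng(6)
        props = _uniform_props(rng, 100, 3)
        x = rng.uniform(1, 5, 100)
        cfg = FitConfig(nonneg_means=False)
        mu, *_ = fit_means(x, props, None, np.ones(100), np.ones(100, bool), cfg)
        ols = np.linalg.lstsq(props.values, x, rcond=None)[0]
        assert np.allclose(mu, ols, atol=1e-9)


class TestFitVariances:
    def test_zero_residuals_give_zero_variances(self):
        rng = np.random.default_rng(7)
        props = _uniform_props(rng, 100, 3)
        mu = np.array([1.0, 2.0, 3.0])
        x = props.values @ mu
        sigma, tau2, _ = fit_variances(
            x, props, (mu, None, None), np.ones(100), np.ones(100, bool), CFG
        )
        assert np.abs(sigma).max() < 1e-6
        assert tau2 < 1e-6

    def test_single_cell_type_matches_scalar_closed_form(self):
        # k=1: v = sigma^2 + tau^2; only the sum is identified, and the
        # penalty splits it; compare the sum against the weighted solve
        rng = np.random.default_rng(8)
        n = 400
        props = ProportionMatrix(np.ones((n, 1)))
        z = 2.0 + rng.standard_normal(n) * 1.3
        weights = rng.uniform(0.5, 2.0, n)
        mask = np.ones(n, bool)
        mu, *_ = fit_means(z, props, None, weights, mask, CFG)
        sigma, tau2, _ = fit_variances(
            z, props, (mu, None, None), weights, mask, CFG
        )
        r2 = (z - mu[0]) ** 2
        expected_total = float(np.sum(weights * r2) / np.sum(weights))
        lam = CFG.l2_penalty * float(np.var(z)) ** 2
        # closed form of min_s sum w (s - r2)^2 + lam * penalty, gauge aside
        assert sigma[0, 0] + tau2 == pytest.approx(expected_total, rel=1e-3)

    def test_k3_recovery_against_gauge_fixed_truth(self):
        # entrywise recovery within 15% of the identified representative
        rng = np.random.default_rng(5)
        n, k = 100_000, 3
        props = _uniform_props(rng, n, k)
        s = np.array([1.0, 2.0, 1.5])
        sigma = np.diag(s)
        signs = [[None, -1, 1], [None, None, -1]]
        for a in range(k):
            for b in range(a + 1, k):
                sigma[a, b] = sigma[b, a] = (
                    signs[a][b] * 0.5 * np.sqrt(s[a] * s[b])
                )
        tau2 = 0.05
        L = np.linalg.cholesky(sigma)
        z = np.array([3.0, 5.0, 2.0]) + rng.standard_normal((n, k)) @ L.T
        x = np.einsum("ih,ih->i", props.values, z) + rng.normal(
            0, np.sqrt(tau2), n
        )
        mask = np.ones(n, bool)
        mu_fit = fit_means(x, props, None, np.ones(n), mask, CFG)
        sigma_fit, _, _ = fit_variances(
            x, props, mu_fit, np.ones(n), mask, CFG
        )
        sigma_star, _ = _gauge_fix(sigma, tau2)
        rel = np.abs(sigma_fit - sigma_star) / np.abs(sigma_star)
        assert rel.max() < 0.15

    def test_fitted_sigma_is_symmetric_psd(self, recovery_study):
        _, fit = recovery_study
        for p in fit.params:
            assert np.max(np.abs(p.sigma - p.sigma.T)) < 1e-10
            assert np.linalg.eigvalsh(p.sigma)[0] >= -1e-8
            assert p.tau2 >= 0.0


class TestUpdateWeights:
    def _residuals(self, pred, first=None):
        first = np.zeros_like(pred) if first is None else first
        return unico.MomentResiduals(first=first, second=pred - first**2)

    def test_homoskedastic_predictions_give_unit_weights(self):
        w = update_weights(self._residuals(np.full(10, 3.0)), CFG)
        assert np.allclose(w, 1.0)

    def test_high_variance_sample_down_weighted_proportionally(self):
        pred = np.array([1.0] * 9 + [100.0])
        w = update_weights(self._residuals(pred), CFG)
        assert w[-1] / w[0] == pytest.approx(0.01, rel=1e-9)

    def test_weights_respect_floor_and_cap(self):
        rng = np.random.default_rng(9)
        pred = 10.0 ** rng.uniform(-12, 12, 1000)
        w = update_weights(self._residuals(pred), CFG)
        assert w.min() >= CFG.weight_floor
        assert w.max() <= CFG.weight_cap


class TestMaskOutliers:
    def test_gaussian_coverage_matches_two_sd(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(100_000)
        kept = mask_outliers(x, CFG).mean()
        assert abs(kept - 0.9545) < 0.005

    def test_constant_vector_keeps_everything(self):
        assert mask_outliers(np.full(10, 2.0), CFG).all()

    def test_single_extreme_point_is_masked(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.standard_normal(200), [200.0]])
        mask = mask_outliers(x, CFG)
        assert not mask[-1]
        assert mask[:-1].mean() > 0.9


class TestFit:
    def test_mean_recovery_on_the_reference_study(self, recovery_study):
        truth, fit = recovery_study
        mu_true = np.array([p.mu for p in truth.params])
        mu_fit = np.array([p.mu for p in fit.params])
        for h in range(3):
            assert robust_correlation(mu_true[:, h], mu_fit[:, h]) >= 0.99

    def test_covariance_entries_track_truth(self, recovery_study):
        truth, fit = recovery_study
        off = np.tril_indices(3, -1)
        ct = np.array([p.sigma[off] for p in truth.params]).ravel()
        cf = np.array([p.sigma[off] for p in fit.params]).ravel()
        assert robust_correlation(ct, cf) > 0.5

    def test_invariant_to_sample_order(self):
        truth = unico.simulate_parametric(n=150, m=8, k=3, seed=31)
        fit_a = unico.fit(truth.bulk, truth.proportions)
        rng = np.random.default_rng(0)
        perm = rng.permutation(150)
        bulk_p = unico.BulkMatrix(
            truth.bulk.values[perm],
            [truth.bulk.sample_ids[i] for i in perm],
            truth.bulk.feature_ids,
        )
        props_p = ProportionMatrix(
            truth.proportions.values[perm],
            bulk_p.sample_ids,
            truth.proportions.cell_type_ids,
        )
        fit_b = unico.fit(bulk_p, props_p)
        for pa, pb in zip(fit_a.params, fit_b.params):
            assert np.abs(pa.mu - pb.mu).max() < 1e-9
            assert np.abs(pa.sigma - pb.sigma).max() < 1e-9

    def test_bit_reproducible(self):
        truth = unico.simulate_parametric(n=120, m=5, k=3, seed=33)
        fit_a = unico.fit(truth.bulk, truth.proportions)
        fit_b = unico.fit(truth.bulk, truth.proportions)
        for pa, pb in zip(fit_a.params, fit_b.params):
            assert np.array_equal(pa.mu, pb.mu)
            assert np.array_equal(pa.sigma, pb.sigma)
            assert pa.tau2 == pb.tau2
        assert np.array_equal(fit_a.sample_weights, fit_b.sample_weights)

    def test_too_few_samples_rejected(self):
        truth = unico.simulate_parametric(n=3, m=2, k=3, seed=35)
        with pytest.raises(ValueError, match="identify"):
            unico.fit(truth.bulk, truth.proportions)

    def test_single_cell_type_matches_sample_moments(self):
        # k=1 degenerates to estimating a location and a total variance
        rng = np.random.default_rng(12)
        n = 300
        x = 3.0 + 0.8 * rng.standard_normal(n)
        bulk = unico.BulkMatrix(x[:, None])
        props = ProportionMatrix(np.ones((n, 1)))
        fit = unico.fit(bulk, props, config=FitConfig(outlier_sd=1e6))
        p = fit.params[0]
        w = fit.sample_weights[0]
        mu_oracle = np.sum(w * x) / np.sum(w)
        var_oracle = np.sum(w * (x - mu_oracle) ** 2) / np.sum(w)
        assert p.mu[0] == pytest.approx(mu_oracle, abs=1e-4)
        assert p.sigma[0, 0] + p.tau2 == pytest.approx(var_oracle, rel=1e-3)
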