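"""The generative-model quantities and the conditional tensor estimator."""
import numpy as np
import pytest

import unico
from unico.containers import (
    BulkMatrix,
    CovariateSet,
    DimensionError,
    FeatureParams,
    ModelFit,
    ProportionMatrix,
)
from unico.core import (
    ablate_covariance,
    baseline_tensor,
    bulk_variance,
    conditional_distribution,
    estimate_tensor,
    estimator_covariance,
    expected_bulk,
)

from oracles import gaussian_conditional


def _props(rows):
    return ProportionMatrix(np.atleast_2d(rows))


def _fit_for(params_list, n):
    m = len(params_list)
    return ModelFit(
        params=params_list,
        sample_weights=np.ones((m, n)),
        outlier_mask=np.ones((m, n), dtype=bool),
        config=unico.FitConfig(),
        diagnostics=[{} for _ in range(m)],
    )


class TestExpectedBulk:
    def test_is_mixture_of_means(self):
        p = FeatureParams([1.0, 2.0], np.zeros((2, 2)), 0.0)
        out = expected_bulk(p, _props([[0.3, 0.7]]))
        assert out == pytest.approx([1.7])

    def test_zero_means_give_zero(self):
        p = FeatureParams([0.0, 0.0], np.zeros((2, 2)), 0.0)
        assert expected_bulk(p, _props([[0.4, 0.6]])) == pytest.approx([0.0])

    def test_cell_level_covariates_enter_inside_the_mixture(self):
        # w=(0.5,0.5), mu=(1,2), c1=(2,), gamma=((0.1),(0.3))
        # -> 0.5*(1+0.2) + 0.5*(2+0.6) = 1.9
        p = FeatureParams(
            [1.0, 2.0], np.zeros((2, 2)), 0.0, gamma=[[0.1], [0.3]]
        )
        cov = CovariateSet(cell_level=[[2.0]])
        out = expected_bulk(p, _props([[0.5, 0.5]]), cov)
        assert out == pytest.approx([1.9])

    def test_dimension_mismatch_names_axis(self):
        p = FeatureParams([1.0, 2.0, 3.0], np.zeros((3, 3)), 0.0)
        with pytest.raises(DimensionError, match="cell types"):
            expected_bulk(p, _props([[0.5, 0.5]]))


class TestBulkVariance:
    @pytest.mark.parametrize(
        "w,sigma,tau2,expected",
        [
            ([0.5, 0.5], np.eye(2), 0.1, 0.6),
            ([0.5, 0.5], np.zeros((2, 2)), 0.3, 0.3),
            ([0.2, 0.8], [[1.0, 0.5], [0.5, 2.0]], 0.0,
             0.04 + 2 * 0.08 + 1.28),
        ],
    )
    def test_quadratic_form(self, w, sigma, tau2, expected):
        p = FeatureParams(np.zeros(2), sigma, tau2)
        assert bulk_variance(p, _props([w])) == pytest.approx([expected])

    def test_matches_bruteforce_expansion(self):
        rng = np.random.default_rng(0)
        k = 4
        a = rng.standard_normal((k, k))
        sigma = a @ a.T
        w = rng.dirichlet(np.ones(k))
        p = FeatureParams(np.zeros(k), sigma, 0.25)
        brute = sum(
            w[i] * w[j] * sigma[i, j] for i in range(k) for j in range(k)
        ) + 0.25
        assert bulk_variance(p, _props([w]))[0] == pytest.approx(brute, abs=1e-12)


class TestConditionalDistribution:
    def test_matches_gaussian_conditioning_oracle(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(300):
            k = int(rng.integers(1, 7))
            a = rng.standard_normal((k, k))
            sigma = a @ a.T + 0.1 * np.eye(k)
            mu = rng.uniform(0, 5, k)
            tau2 = float(rng.uniform(0.01, 1.0))
            w = rng.dirichlet(np.ones(k))
            x = float(rng.normal(w @ mu, 1.0))
            p = FeatureParams(mu, sigma, tau2)
            mean, cov = conditional_distribution(p, w, x)
            omean, ocov = gaussian_conditional(mu, sigma, tau2, w, x)
            worst = max(
                worst,
                np.abs(mean - omean).max(),
                np.abs(cov - ocov).max(),
            )
        assert worst < 1e-10

    def test_uninformative_bulk_leaves_prior_covariance(self):
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        p = FeatureParams([1.0, 2.0], sigma, 1e12)
        _, cov = conditional_distribution(p, [0.5, 0.5], 10.0)
        assert np.allclose(cov, sigma, atol=1e-10)

    def test_single_cell_type_noiseless_is_exact(self):
        p = FeatureParams([3.0], [[4.0]], 0.0)
        mean, cov = conditional_distribution(p, [1.0], 5.0)
        assert mean == pytest.approx([5.0])
        assert np.allclose(cov, 0.0, atol=1e-12)

    def test_posterior_never_widens(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            a = rng.standard_normal((k, k))
            sigma = a @ a.T + 0.1 * np.eye(k)
            p = FeatureParams(np.zeros(k), sigma, 0.3)
            _, cov = conditional_distribution(p, rng.dirichlet(np.ones(k)), 1.0)
            assert np.linalg.eigvalsh(cov)[0] > -1e-10
            assert np.linalg.eigvalsh(sigma - cov)[0] > -1e-10


class TestEstimateTensor:
    def _study(self, rng, n=20, m=5, k=3, tau2=0.2):
        params = []
        for _ in range(m):
            a = rng.standard_normal((k, k))
            params.append(
                FeatureParams(rng.uniform(0, 5, k), a @ a.T, tau2)
            )
        W = rng.dirichlet(np.ones(k), size=n)
        X = rng.uniform(0, 5, (n, m))
        return (
            BulkMatrix(X),
            ProportionMatrix(W),
            _fit_for(params, n),
        )

    def test_zero_residual_returns_prior_mean(self):
        p = FeatureParams([1.0, 2.0], np.eye(2), 0.5)
        props = _props([[0.3, 0.7]])
        bulk = BulkMatrix([[1.7]])
        z = estimate_tensor(bulk, props, _fit_for([p], 1))
        assert z.values[0, 0] == pytest.approx([1.0, 2.0])

    def test_zero_covariance_returns_prior_mean(self):
        p = FeatureParams([1.0, 2.0], np.zeros((2, 2)), 0.4)
        z = estimate_tensor(
            BulkMatrix([[9.0]]), _props([[0.3, 0.7]]), _fit_for([p], 1)
        )
        assert z.values[0, 0] == pytest.approx([1.0, 2.0])

    def test_identity_covariance_noiseless_case(self):
        # mu=(1,2), Sigma=I, tau2=0, w=(.5,.5), x=2 -> (1.5, 2.5)
        p = FeatureParams([1.0, 2.0], np.eye(2), 0.0)
        z = estimate_tensor(
            BulkMatrix([[2.0]]), _props([[0.5, 0.5]]), _fit_for([p], 1)
        )
        assert z.values[0, 0] == pytest.approx([1.5, 2.5])
        assert z.values[0, 0] @ np.array([0.5, 0.5]) == pytest.approx(2.0)

    def test_noiseless_reconstruction_is_exact(self):
        rng = np.random.default_rng(7)
        bulk, props, fit = self._study(rng, tau2=0.0)
        z = estimate_tensor(bulk, props, fit)
        recon = np.einsum("ih,ijh->ij", props.values, z.values)
        assert np.abs(recon - bulk.values).max() < 1e-9

    def test_degenerate_denominator_falls_back_to_prior(self, caplog):
        p = FeatureParams([1.0, 2.0], np.zeros((2, 2)), 0.0)
        with caplog.at_level("WARNING", logger="unico"):
            z = estimate_tensor(
                BulkMatrix([[5.0]]), _props([[0.5, 0.5]]), _fit_for([p], 1)
            )
        assert z.values[0, 0] == pytest.approx([1.0, 2.0])
        assert any("degenerate" in r.message for r in caplog.records)

    def test_permutation_equivariance_over_cell_types(self):
        rng = np.random.default_rng(11)
        bulk, props, fit = self._study(rng)
        z = estimate_tensor(bulk, props, fit)
        perm = np.array([2, 0, 1])
        props_p = ProportionMatrix(
            props.values[:, perm],
            list(props.sample_ids),
            [props.cell_type_ids[i] for i in perm],
        )
        fit_p = _fit_for(
            [
                FeatureParams(p.mu[perm], p.sigma[np.ix_(perm, perm)], p.tau2)
                for p in fit.params
            ],
            bulk.n_samples,
        )
        z_p = estimate_tensor(bulk, props_p, fit_p)
        # reordering permutes summation order, so exact bit equality is not
        # guaranteed; agreement is to floating-point rounding
        assert np.allclose(z_p.values, z.values[:, :, perm], rtol=0, atol=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(13)
        bulk, props, fit = self._study(rng)
        c = 3.7
        bulk_c = BulkMatrix(c * bulk.values)
        fit_c = _fit_for(
            [
                FeatureParams(c * p.mu, c * c * p.sigma, c * c * p.tau2)
                for p in fit.params
            ],
            bulk.n_samples,
        )
        z = estimate_tensor(bulk, props, fit)
        z_c = estimate_tensor(bulk_c, props, fit_c)
        assert np.abs(z_c.values - c * z.values).max() < 1e-9

    def test_estimates_lie_on_the_sigma_w_line(self):
        rng = np.random.default_rng(17)
        bulk, props, fit = self._study(rng)
        z = estimate_tensor(bulk, props, fit)
        for j, p in enumerate(fit.params):
            for i in range(bulk.n_samples):
                d = z.values[i, j] - p.mu
                direction = p.sigma @ props.values[i]
                # collinearity: residual after projecting onto the direction
                proj = direction * (d @ direction) / (direction @ direction)
                assert np.abs(d - proj).max() < 1e-9


class TestBaselineTensor:
    def test_is_the_elementwise_product(self):
        z = baseline_tensor(BulkMatrix([[2.0]]), _props([[0.25, 0.75]]))
        assert z.values[0, 0] == pytest.approx([0.5, 1.5])

    def test_zero_weight_gives_zero_level(self):
        z = baseline_tensor(BulkMatrix([[3.0]]), _props([[0.0, 1.0]]))
        assert z.values[0, 0, 0] == 0.0

    def test_summing_over_cell_types_recovers_bulk(self):
        rng = np.random.default_rng(19)
        bulk = BulkMatrix(rng.uniform(0, 5, (10, 4)))
        props = ProportionMatrix(rng.dirichlet(np.ones(3), size=10))
        z = baseline_tensor(bulk, props)
        assert np.allclose(z.values.sum(axis=2), bulk.values)


class TestEstimatorCovariance:
    def test_identity_ablation_is_feature_constant(self):
        rng = np.random.default_rng(23)
        n, k = 100, 3
        props = ProportionMatrix(rng.dirichlet(np.ones(k), size=n))
        covs = []
        for _ in range(5):
            a = rng.standard_normal((k, k))
            p = FeatureParams(np.zeros(k), a @ a.T, 0.0)
            ablated = FeatureParams(np.zeros(k), np.eye(k), 0.0)
            covs.append(estimator_covariance(ablated, props))
        for c in covs[1:]:
            assert np.array_equal(c, covs[0])

    def test_ablate_covariance_modes(self):
        p = FeatureParams([1.0, 2.0], [[2.0, 0.7], [0.7, 1.0]], 0.3)
        fit = _fit_for([p], 4)
        ident = ablate_covariance(fit, "identity")
        assert np.array_equal(ident.params[0].sigma, np.eye(2))
        assert ident.params[0].tau2 == 0.0
        diag = ablate_covariance(fit, "diagonal")
        assert np.array_equal(
            diag.params[0].sigma, np.diag([2.0, 1.0])
        )
        assert diag.params[0].tau2 == 0.3
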