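"""Generative model quantities and the closed-form conditional tensor estimator.

The model treats each bulk measurement as a proportion-weighted combination of
latent per-sample cell-type levels plus i.i.d. measurement noise:

    X_ij = w_i^T Z_ij + e_ij,      Z_ij = mu_j + eps_ij,
    Var[e_ij] = tau_j^2,           Var[eps_ij] = Sigma_j  (k x k, PSD).

Given fitted per-feature parameters theta_j = {mu_j, Sigma_j, tau_j^2}, the
cell-type-level tensor is estimated by the expected value of the conditional
distribution Z_ij | theta_j, X_ij = x_ij, w_i, which has the closed form

    zhat_ij = E[Z_ij | theta_j]
              + Sigma_j w_i (x_ij - E[X_ij]) / (w_i^T Sigma_j w_i + tau_j^2).

The residual between observed and expected bulk is distributed back to the
cell types along the direction Sigma_j w_i, so the cell-type covariance
structure — not only the proportions — shapes the deconvolution. Covariates
enter the conditional mean per cell type (cell-level block) and the bulk
expectation additively (tissue-level block).
"""
from __future__ import annotations

import logging

import numpy as np

from .containers import (
    EMPTY_COVARIATES,
    BulkMatrix,
    CellTensor,
    CovariateSet,
    DimensionError,
    FeatureParams,
    ModelFit,
    ProportionMatrix,
)

logger = logging.getLogger("unico")

#: below this, the conditional denominator is treated as degenerate and the
#: estimator falls back to the prior mean (no deconvolvable signal)
DEGENERATE_DENOMINATOR = 1e-12


def _check_k(params: FeatureParams, proportions: ProportionMatrix) -> None:
    if params.k != proportions.n_cell_types:
        raise DimensionError(
            f"params have k={params.k} cell types but proportions have "
            f"k={proportions.n_cell_types}"
        )


def conditional_cell_means(
    params: FeatureParams,
    n: int,
    covariates: CovariateSet | None = None,
) -> np.ndarray:
    """Per-sample prior cell-type means E[Z_ij | theta_j], shape (n, k).

    Without covariates every row is ``mu``. With cell-level covariates the
    mean of cell type h for sample i is ``mu_h + c1_i^T gamma_h``.
    """
    cov = covariates or EMPTY_COVARIATES
    means = np.tile(params.mu, (n, 1))
    if cov.p1 and params.gamma is not None:
        cov.check_samples(n)
        if params.gamma.shape[1] != cov.p1:
            raise DimensionError(
                f"gamma has {params.gamma.shape[1]} covariate columns; "
                f"cell-level covariates have {cov.p1}"
            )
        means = means + cov.cell_level @ params.gamma.T
    return means


def expected_bulk(
    params: FeatureParams,
    proportions: ProportionMatrix,
    covariates: CovariateSet | None = None,
) -> np.ndarray:
    """Model-implied bulk expectation E[X_ij] per sample (length n).

    E[X_ij] = sum_h w_ih (mu_jh + c1_i^T gamma_jh) + c2_i^T beta_j; reduces to
    W @ mu when covariates are absent.
    """
    _check_k(params, proportions)
    cov = covariates or EMPTY_COVARIATES
    n = proportions.n_samples
    cov.check_samples(n)
    cell_means = conditional_cell_means(params, n, cov)
    out = np.einsum("ih,ih->i", proportions.values, cell_means)
    if cov.p2 and params.beta is not None:
        if params.beta.shape[0] != cov.p2:
            raise DimensionError(
                f"beta has length {params.beta.shape[0]}; tissue-level "
                f"covariates have {cov.p2} columns"
            )
        out = out + cov.tissue_level @ params.beta
    return out


def bulk_variance(
    params: FeatureParams, proportions: ProportionMatrix
) -> np.ndarray:
    """Model-implied bulk variance w_i^T Sigma_j w_i + tau_j^2 per sample.

    Equivalently Sum((w_i w_i^T) o Sigma_j) + tau_j^2 with o the Hadamard
    product; strictly positive whenever tau_j^2 > 0.
    """
    _check_k(params, proportions)
    if np.linalg.eigvalsh(params.sigma)[0] < -1e-8:
        raise ValueError("sigma is not positive semidefinite")
    W = proportions.values
    return np.einsum("ih,hg,ig->i", W, params.sigma, W) + params.tau2


def conditional_distribution(
    params: FeatureParams, w: np.ndarray, x: float
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of Z | theta, X = x, w for one observation.

    Returns ``(mean, cov)`` where ``mean`` is the tensor estimate and
    ``cov = Sigma - (Sigma w)(Sigma w)^T / (w^T Sigma w + tau^2)`` is the
    remaining cell-type-level uncertainty once the bulk value is known.
    """
    w = np.asarray(w, dtype=float).reshape(-1)
    if w.shape[0] != params.k:
        raise DimensionError(
            f"proportion vector has length {w.shape[0]}; params have k={params.k}"
        )
    sw = params.sigma @ w
    den = float(w @ sw + params.tau2)
    if den <= DEGENERATE_DENOMINATOR:
        logger.warning(
            "degenerate conditional denominator (%.3g); returning prior", den
        )
        return params.mu.copy(), params.sigma.copy()
    mean = params.mu + sw * (float(x) - float(w @ params.mu)) / den
    cov = params.sigma - np.outer(sw, sw) / den
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def estimate_tensor(
    bulk: BulkMatrix,
    proportions: ProportionMatrix,
    fit: ModelFit,
    covariates: CovariateSet | None = None,
) -> CellTensor:
    """Deconvolve bulk into the (sample, feature, cell_type) tensor.

    Applies the closed-form conditional-mean estimator feature by feature
    using the fitted parameters. Features with a degenerate denominator
    (w^T Sigma w + tau^2 ~ 0) fall back to the prior cell-type means and are
    logged — such features carry no deconvolvable signal.
    """
    if bulk.n_samples != proportions.n_samples:
        raise DimensionError(
            f"bulk has {bulk.n_samples} samples but proportions have "
            f"{proportions.n_samples}"
        )
    if fit.n_features != bulk.n_features:
        raise DimensionError(
            f"fit covers {fit.n_features} features but bulk has {bulk.n_features}"
        )
    cov = covariates or EMPTY_COVARIATES
    n, m = bulk.n_samples, bulk.n_features
    k = proportions.n_cell_types
    W = proportions.values
    out = np.empty((n, m, k))
    n_degenerate = 0
    for j in range(m):
        p = fit.params[j]
        _check_k(p, proportions)
        prior = conditional_cell_means(p, n, cov)
        sw = W @ p.sigma  # (n, k) rows Sigma w_i
        den = np.einsum("ih,ih->i", W, sw) + p.tau2
        resid = bulk.values[:, j] - expected_bulk(p, proportions, cov)
        degen = den <= DEGENERATE_DENOMINATOR
        safe_den = np.where(degen, 1.0, den)
        z = prior + sw * np.where(degen, 0.0, resid / safe_den)[:, None]
        n_degenerate += int(degen.sum())
        out[:, j, :] = z
    if n_degenerate:
        logger.warning(
            "%d (sample, feature) pairs had degenerate denominators; "
            "prior means returned for those entries", n_degenerate,
        )
    return CellTensor(
        out,
        sample_ids=bulk.sample_ids,
        feature_ids=bulk.feature_ids,
        cell_type_ids=proportions.cell_type_ids,
    )


def baseline_tensor(bulk: BulkMatrix, proportions: ProportionMatrix) -> CellTensor:
    """Naive deconvolution baseline: z_ijh = x_ij * w_ih."""
    if bulk.n_samples != proportions.n_samples:
        raise DimensionError(
            f"bulk has {bulk.n_samples} samples but proportions have "
            f"{proportions.n_samples}"
        )
    values = bulk.values[:, :, None] * proportions.values[:, None, :]
    return CellTensor(
        values,
        sample_ids=bulk.sample_ids,
        feature_ids=bulk.feature_ids,
        cell_type_ids=proportions.cell_type_ids,
    )


def estimator_covariance(
    params: FeatureParams, proportions: ProportionMatrix
) -> np.ndarray:
    """Model-implied across-sample covariance of the tensor estimates.

    For fixed theta the estimator is linear in X, so over the sampling of X
    its covariance for sample i is (Sigma w_i)(Sigma w_i)^T / (w_i^T Sigma
    w_i + tau^2); averaging over samples gives the large-sample cell-type
    covariance that the estimated tensor exhibits. Under a Sigma = I, tau^2
    = 0 ablation this quantity is identical for every feature, whereas under
    the full model it tracks Sigma_j — the qualitative reason covariance
    modeling is needed to recover covariance structure.
    """
    _check_k(params, proportions)
    W = proportions.values
    sw = W @ params.sigma
    den = np.einsum("ih,ih->i", W, sw) + params.tau2
    den = np.where(den <= DEGENERATE_DENOMINATOR, np.inf, den)
    return np.einsum("ih,ig,i->hg", sw, sw, 1.0 / den) / W.shape[0]


def ablate_covariance(fit: ModelFit, mode: str = "identity") -> ModelFit:
    """Return a copy of ``fit`` with each feature's covariance replaced.

    ``mode='identity'`` sets Sigma_j = I_k and tau_j^2 = 0 (the
    no-covariance-modeling ablation); ``mode='diagonal'`` keeps the fitted
    per-cell-type variances but zeroes the covariances.
    """
    if mode not in ("identity", "diagonal"):
        raise ValueError("mode must be 'identity' or 'diagonal'")
    params = []
    for p in fit.params:
        if mode == "identity":
            sigma, tau2 = np.eye(p.k), 0.0
        else:
            sigma, tau2 = np.diag(np.diag(p.sigma)), p.tau2
        params.append(
            FeatureParams(p.mu.copy(), sigma, tau2,
                          gamma=None if p.gamma is None else p.gamma.copy(),
                          beta=None if p.beta is None else p.beta.copy())
        )
    return ModelFit(
        params=params,
        sample_weights=fit.sample_weights.copy(),
        outlier_mask=fit.outlier_mask.copy(),
        config=fit.config,
        diagnostics=[dict(d) for d in fit.diagnostics],
        feature_ids=list(fit.feature_ids),
        sample_ids=list(fit.sample_ids),
        cell_type_ids=list(fit.cell_type_ids),
    )
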