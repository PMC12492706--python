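"""Per-feature parameter estimation by iteratively re-weighted moment matching.

Estimation follows a generalized-method-of-moments recipe with one pair of
sample-specific moment conditions per sample:

    first_i  = E[X_ij] - x_ij
    second_i = Var[X_ij] - (x_ij - E[X_ij])^2

Both have expectation zero at the true parameters. With a diagonal weight
matrix the objective reduces to weighted least squares. The first moment is
linear in (mu, gamma, beta) and is solved under a non-negativity constraint
on the means; the second moment is linear in the free entries of (Sigma,
tau^2), so the L2-penalized objective is solved in closed form, with a
Cholesky-parameterized smooth refinement whenever the closed-form solution
leaves the PSD / nonnegative-noise feasible set. Samples more than
``outlier_sd`` standard deviations from the per-feature mean are masked once,
up front; between iterations samples are re-weighted by the inverse of their
model-predicted variance so that poorly predicted samples are down-weighted.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import scipy.optimize

from .containers import (
    EMPTY_COVARIATES,
    BulkMatrix,
    CovariateSet,
    DimensionError,
    FeatureParams,
    FitConfig,
    ModelFit,
    MomentResiduals,
    ProportionMatrix,
)
from .core import bulk_variance, expected_bulk

logger = logging.getLogger("unico")

_VAR_EPS = 1e-12


# ---------------------------------------------------------------------------
# moment conditions and weights

def moment_conditions(
    params: FeatureParams,
    x_feature: np.ndarray,
    proportions: ProportionMatrix,
    covariates: CovariateSet | None = None,
) -> MomentResiduals:
    """First/second moment-condition residuals for one feature."""
    x = np.asarray(x_feature, dtype=float).reshape(-1)
    if x.shape[0] != proportions.n_samples:
        raise DimensionError(
            f"feature vector has {x.shape[0]} samples; proportions have "
            f"{proportions.n_samples}"
        )
    mean = expected_bulk(params, proportions, covariates)
    var = bulk_variance(params, proportions)
    first = mean - x
    second = var - (x - mean) ** 2
    return MomentResiduals(first=first, second=second)


def update_weights(residuals: MomentResiduals, config: FitConfig) -> np.ndarray:
    """Inverse predicted-variance sample weights, clipped and mean-normalized.

    The predicted variance is recovered as ``second + first^2``; weights are
    ``1 / max(pred, eps)`` clipped to ``[weight_floor, weight_cap]`` and
    scaled to mean 1 (re-clipped so the bounds are a hard contract).
    """
    pred = residuals.second + residuals.first**2
    u = 1.0 / np.maximum(pred, _VAR_EPS)
    u = np.clip(u, config.weight_floor, config.weight_cap)
    u = u / u.mean()
    return np.clip(u, config.weight_floor, config.weight_cap)


def mask_outliers(x_feature: np.ndarray, config: FitConfig) -> np.ndarray:
    """True for samples within ``outlier_sd`` SDs of the per-feature mean.

    Computed once from the raw feature values; a zero-variance feature keeps
    every sample.
    """
    x = np.asarray(x_feature, dtype=float).reshape(-1)
    if x.shape[0] < 3:
        raise ValueError("outlier masking requires at least 3 samples")
    sd = float(np.std(x))
    if sd == 0.0:
        return np.ones(x.shape[0], dtype=bool)
    return np.abs(x - x.mean()) <= config.outlier_sd * sd


# ---------------------------------------------------------------------------
# first moment: constrained weighted least squares for (mu, gamma, beta)

def _mean_design(
    W: np.ndarray, covariates: CovariateSet
) -> tuple[np.ndarray, int, int, int]:
    """Design matrix [W | W*c1_p ... | C2] and the block sizes (k, k*p1, p2)."""
    k = W.shape[1]
    blocks = [W]
    if covariates.p1:
        for p in range(covariates.p1):
            blocks.append(W * covariates.cell_level[:, p][:, None])
    if covariates.p2:
        blocks.append(covariates.tissue_level)
    return np.hstack(blocks), k, k * covariates.p1, covariates.p2


def fit_means(
    x_feature: np.ndarray,
    proportions: ProportionMatrix,
    covariates: CovariateSet | None,
    weights: np.ndarray,
    mask: np.ndarray,
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Weighted least-squares fit of (mu, gamma, beta) with mu >= 0.

    Cell-type means are constrained nonnegative when ``config.nonneg_means``;
    covariate effects are unconstrained. A rank-deficient design triggers a
    small ridge-regularized solve with a logged warning.
    """
    cov = covariates or EMPTY_COVARIATES
    x = np.asarray(x_feature, dtype=float).reshape(-1)
    W = proportions.values
    cov.check_samples(W.shape[0])
    D, k, ng, p2 = _mean_design(W, cov)
    use = np.asarray(mask, dtype=bool)
    if use.sum() < D.shape[1]:
        raise ValueError(
            f"only {int(use.sum())} unmasked samples for {D.shape[1]} mean "
            "parameters"
        )
    sw = np.sqrt(np.asarray(weights, dtype=float)[use])
    A = D[use] * sw[:, None]
    y = x[use] * sw

    if np.linalg.matrix_rank(A, tol=None) < A.shape[1]:
        logger.warning("rank-deficient mean design; applying ridge regularization")
        ridge = math.sqrt(1e-8 * max(float(np.mean(A**2)), _VAR_EPS))
        A = np.vstack([A, ridge * np.eye(A.shape[1])])
        y = np.concatenate([y, np.zeros(A.shape[1])])

    if config.nonneg_means:
        if ng + p2 == 0:
            coef, _ = scipy.optimize.nnls(A, y)
        else:
            lb = np.concatenate([np.zeros(k), np.full(ng + p2, -np.inf)])
            ub = np.full(k + ng + p2, np.inf)
            coef = scipy.optimize.lsq_linear(A, y, bounds=(lb, ub)).x
    else:
        coef = np.linalg.lstsq(A, y, rcond=None)[0]

    mu = coef[:k]
    gamma = coef[k : k + ng].reshape(cov.p1, k).T if ng else None
    beta = coef[k + ng :] if p2 else None
    return mu, gamma, beta


# ---------------------------------------------------------------------------
# second moment: penalized fit of (Sigma, tau^2)

def _vech_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.tril_indices(k)
    return rows, cols


def _second_moment_design(W: np.ndarray) -> np.ndarray:
    """Rows q_i with v_i = q_i @ vech(Sigma) + tau2; off-diagonals doubled."""
    k = W.shape[1]
    rows, cols = _vech_indices(k)
    Q = W[:, rows] * W[:, cols]
    Q[:, rows != cols] *= 2.0
    return Q


def _penalty_diag(k: int) -> np.ndarray:
    rows, cols = _vech_indices(k)
    p = np.where(rows == cols, 1.0, 2.0)
    return np.concatenate([p, [1.0]])


def _refine_psd(
    Q: np.ndarray,
    y: np.ndarray,
    u: np.ndarray,
    lam: float,
    sigma0: np.ndarray,
    tau0: float,
    config: FitConfig,
) -> tuple[np.ndarray, float, bool]:
    """Minimize the penalized second-moment objective over Sigma = L L^T,
    tau^2 = t^2 (PSD and nonnegativity by construction), via L-BFGS-B with
    analytic gradients, starting from the eigenvalue-clipped closed-form
    solution."""
    k = sigma0.shape[0]
    rows, cols = _vech_indices(k)
    evals, evecs = np.linalg.eigh(0.5 * (sigma0 + sigma0.T))
    evals = np.clip(evals, 0.0, None)
    proj = (evecs * evals) @ evecs.T
    jitter = 1e-10 * max(float(evals.max()), 1.0)
    L0 = np.linalg.cholesky(proj + jitter * np.eye(k))
    t0 = math.sqrt(max(tau0, 0.0))
    z0 = np.concatenate([L0[rows, cols], [t0]])
    W2 = Q  # rows already encode w_a w_b (doubled off-diagonal)

    def unpack(z):
        L = np.zeros((k, k))
        L[rows, cols] = z[:-1]
        return L, z[-1]

    def fun_grad(z):
        L, t = unpack(z)
        sigma = L @ L.T
        tau2 = t * t
        svech = sigma[rows, cols]
        v = W2 @ svech + tau2
        e = v - y
        ue = u * e
        f = float(e @ ue) + lam * (
            float(np.sum(sigma**2)) + tau2 * tau2
        )
        # gradient wrt Sigma as a full symmetric matrix
        G = np.zeros((k, k))
        coef = 2.0 * ue @ Q  # d f / d vech(Sigma), doubling already in Q
        G[rows, cols] += coef
        G[cols, rows] += coef
        G /= 2.0
        G += 2.0 * lam * sigma
        gL = 2.0 * (G @ L)
        gt = (2.0 * float(np.sum(ue)) + 2.0 * lam * tau2) * 2.0 * t
        return f, np.concatenate([gL[rows, cols], [gt]])

    res = scipy.optimize.minimize(
        fun_grad,
        z0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12,
                 "maxfun": config.max_evals},
    )
    L, t = unpack(res.x)
    sigma = L @ L.T
    sigma, tau2 = _gauge_fix(0.5 * (sigma + sigma.T), float(t * t))
    # L-BFGS termination flags 1/2 (precision-limited) are acceptable here
    ok = res.status in (0, 1, 2) and np.all(np.isfinite(res.x))
    return sigma, max(tau2, 0.0), ok


def _gauge_fix(sigma: np.ndarray, tau2: float) -> tuple[np.ndarray, float]:
    """Pin the simplex-induced flat direction of the second moment.

    When proportion rows sum to 1, (Sigma + c 11^T, tau^2 - c) predicts the
    same bulk variance for every c, so the data cannot choose c; the L2
    penalty does. This selects the feasible c minimizing
    ||Sigma + c 11^T||_F^2 + (tau^2 - c)^2 in closed form, making the
    reported parameters unique and independent of optimizer path.
    """
    k = sigma.shape[0]
    c = (tau2 - float(sigma.sum())) / (k * k + 1)
    c = min(c, tau2)
    if c < 0.0:
        # keep Sigma + c 11^T PSD: bisect down to the boundary
        ones = np.ones((k, k))
        lo, hi = c, 0.0
        if np.linalg.eigvalsh(sigma + c * ones)[0] < 0:
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if np.linalg.eigvalsh(sigma + mid * ones)[0] < 0:
                    lo = mid
                else:
                    hi = mid
            c = hi
    return sigma + c * np.ones((k, k)), tau2 - c


def fit_variances(
    x_feature: np.ndarray,
    proportions: ProportionMatrix,
    means: tuple[np.ndarray, np.ndarray | None, np.ndarray | None],
    weights: np.ndarray,
    mask: np.ndarray,
    config: FitConfig,
    covariates: CovariateSet | None = None,
) -> tuple[np.ndarray, float, dict]:
    """Penalized weighted fit of (Sigma, tau^2) given fitted means.

    Minimizes sum_i u_i [(w_i^T Sigma w_i + tau^2) - r_i^2]^2 +
    lambda (||Sigma||_F^2 + tau^4) over the free entries of Sigma and tau^2,
    subject to Sigma PSD and tau^2 >= 0. The unconstrained penalized problem
    is quadratic and solved exactly; the constrained refinement (Cholesky
    parameterization) runs only if that solution is infeasible.
    """
    cov = covariates or EMPTY_COVARIATES
    x = np.asarray(x_feature, dtype=float).reshape(-1)
    mu, gamma, beta = means
    k = proportions.n_cell_types
    probe = FeatureParams(
        np.asarray(mu, float), np.zeros((k, k)), 0.0, gamma=gamma, beta=beta
    )
    r = x - expected_bulk(probe, proportions, cov)
    use = np.asarray(mask, dtype=bool)
    u = np.asarray(weights, dtype=float)[use]
    Q = _second_moment_design(proportions.values[use])
    A = np.hstack([Q, np.ones((Q.shape[0], 1))])
    y = r[use] ** 2

    scale = float(np.var(x[use]))
    lam = config.l2_penalty * scale**2 + _VAR_EPS
    P = _penalty_diag(k)
    H = (A * u[:, None]).T @ A + lam * np.diag(P)
    g = (A * u[:, None]).T @ y
    coef = np.linalg.solve(H, g)

    rows, cols = _vech_indices(k)
    sigma = np.zeros((k, k))
    sigma[rows, cols] = coef[:-1]
    sigma[cols, rows] = coef[:-1]
    tau2 = float(coef[-1])

    diag = {"refined": False, "converged": True}
    min_eig = float(np.linalg.eigvalsh(sigma)[0]) if k else 0.0
    if min_eig < -1e-10 or tau2 < 0.0:
        sigma, tau2, ok = _refine_psd(Q, y, u, lam, sigma, tau2, config)
        diag = {"refined": True, "converged": ok}
        if not ok:
            logger.warning("variance refinement did not fully converge")
    else:
        tau2 = max(tau2, 0.0)
    # guard against roundoff just below the PSD tolerance
    min_eig = float(np.linalg.eigvalsh(sigma)[0]) if k else 0.0
    if min_eig < 0.0:
        sigma = sigma + (1e-12 - min_eig) * np.eye(k)
    v = A @ np.concatenate([sigma[rows, cols], [tau2]])
    diag["objective"] = float(u @ (v - y) ** 2 + lam * (
        np.sum(sigma**2) + tau2**2))
    return sigma, tau2, diag


# ---------------------------------------------------------------------------
# full per-feature pipeline

def _fit_feature(
    x: np.ndarray,
    proportions: ProportionMatrix,
    covariates: CovariateSet,
    config: FitConfig,
) -> tuple[FeatureParams, np.ndarray, np.ndarray, dict]:
    n = x.shape[0]
    k = proportions.n_cell_types
    mask = mask_outliers(x, config)
    min_needed = max(k + covariates.p1 + covariates.p2 + 1, math.ceil(0.5 * n))
    diag: dict = {"flagged": bool(mask.sum() < min_needed)}
    weights = np.ones(n)
    mu = np.zeros(k)
    gamma = beta = None
    sigma, tau2 = np.zeros((k, k)), 0.0
    for _ in range(config.mean_iterations):
        mu, gamma, beta = fit_means(
            x, proportions, covariates, weights, mask, config
        )
        sigma, tau2, vdiag = fit_variances(
            x, proportions, (mu, gamma, beta), weights, mask, config, covariates
        )
        params = FeatureParams(mu, sigma, tau2, gamma=gamma, beta=beta)
        weights = update_weights(
            moment_conditions(params, x, proportions, covariates), config
        )
    for _ in range(config.var_iterations):
        sigma, tau2, vdiag = fit_variances(
            x, proportions, (mu, gamma, beta), weights, mask, config, covariates
        )
        params = FeatureParams(mu, sigma, tau2, gamma=gamma, beta=beta)
        weights = update_weights(
            moment_conditions(params, x, proportions, covariates), config
        )
    diag.update(vdiag)
    return params, weights, mask, diag


def fit(
    bulk: BulkMatrix,
    proportions: ProportionMatrix,
    covariates: CovariateSet | None = None,
    config: FitConfig | None = None,
) -> ModelFit:
    """Fit per-feature parameters for every feature of ``bulk``.

    Features are processed independently (results do not depend on feature
    order or batching); the whole procedure is deterministic for a given
    config. Features whose fit fails a precondition are flagged in the
    diagnostics and carry zeroed parameters.
    """
    cov = covariates or EMPTY_COVARIATES
    config = config or FitConfig()
    if bulk.n_samples != proportions.n_samples:
        raise DimensionError(
            f"bulk has {bulk.n_samples} samples but proportions have "
            f"{proportions.n_samples}"
        )
    cov.check_samples(bulk.n_samples)
    n, k = bulk.n_samples, proportions.n_cell_types
    if n <= k + cov.p1 * k + cov.p2:
        raise ValueError(
            f"n={n} samples cannot identify {k + cov.p1 * k + cov.p2} mean "
            "parameters"
        )
    if bulk.values.size and bulk.values.max() < 50:
        logger.warning(
            "bulk maximum is %.3g (< 50); if these are log-scale expression "
            "values, note that log-scaling breaks the linear mixing "
            "assumption — inputs are never transformed automatically",
            float(bulk.values.max()),
        )
    # canonical internal sample order: results are exactly invariant to the
    # order in which samples arrive (fitting has no other order dependence)
    order = np.argsort(np.asarray(bulk.sample_ids, dtype=object))
    inverse = np.argsort(order)
    props_sorted = ProportionMatrix(
        proportions.values[order],
        [proportions.sample_ids[i] for i in order],
        list(proportions.cell_type_ids),
    )
    cov_sorted = CovariateSet(
        None if cov.cell_level is None else cov.cell_level[order],
        None if cov.tissue_level is None else cov.tissue_level[order],
        cov.cell_level_names,
        cov.tissue_level_names,
    )
    params_list, weights_rows, mask_rows, diags = [], [], [], []
    for j in range(bulk.n_features):
        x = bulk.values[order, j]
        try:
            params, weights, mask, diag = _fit_feature(
                x, props_sorted, cov_sorted, config
            )
            weights, mask = weights[inverse], mask[inverse]
        except Exception as exc:  # noqa: BLE001 - feature-level containment
            logger.warning("feature %s skipped: %s", bulk.feature_ids[j], exc)
            params = FeatureParams(np.zeros(k), np.zeros((k, k)), 0.0)
            weights, mask = np.ones(n), np.ones(n, dtype=bool)
            diag = {"flagged": True, "error": str(exc)}
        params_list.append(params)
        weights_rows.append(weights)
        mask_rows.append(mask)
        diags.append(diag)
    return ModelFit(
        params=params_list,
        sample_weights=np.array(weights_rows),
        outlier_mask=np.array(mask_rows),
        config=config,
        diagnostics=diags,
        feature_ids=bulk.feature_ids,
        sample_ids=bulk.sample_ids,
        cell_type_ids=proportions.cell_type_ids,
    )
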