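"""Evaluation statistics for deconvolution quality.

Includes the robust (outlier-trimmed) linear correlation used throughout the
package's benchmarks, the normalized von Neumann entropy that quantifies how
much cell-type covariance structure a feature carries, the root-median-square
error, the delta-log10(p) "information beyond bulk" regression metric, the
moment-recovery scoring against trimmed gold-standard moments, and the
effect-beyond-composition regression that separates a phenotype's effect on
cell-type levels from its effect through cell composition.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.covariance import MinCovDet

from .containers import CellTensor, EntropyReport, ModelFit, ProportionMatrix

logger = logging.getLogger("unico")


def robust_correlation(
    a: np.ndarray, b: np.ndarray, trim: float = 0.05, random_state: int = 0
) -> float:
    """Outlier-trimmed linear correlation of two vectors.

    Fits a minimum-covariance-determinant robust covariance on the best
    ``(1 - trim)`` fraction of the points (an approximate search for the
    subset minimizing the Gaussian confidence ellipsoid) and returns the
    implied Pearson correlation. If either vector has interquartile range 0
    the correlation is defined to be 0.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"vectors have lengths {a.shape[0]} and {b.shape[0]}"
        )
    n = a.shape[0]
    if n < 5:
        raise ValueError("robust correlation requires at least 5 points")
    if stats.iqr(a) == 0.0 or stats.iqr(b) == 0.0:
        return 0.0
    X = np.column_stack([a, b])
    support = min(max(1.0 - trim, (n + 3 + 1) / (2 * n)), 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # degenerate-rank notice
        mcd = MinCovDet(
            support_fraction=support, random_state=random_state
        ).fit(X)
    c = mcd.covariance_
    if c[0, 0] <= 0 or c[1, 1] <= 0:
        return 0.0
    r = c[0, 1] / np.sqrt(c[0, 0] * c[1, 1])
    return float(np.clip(r, -1.0, 1.0))


def von_neumann_entropy(cov: np.ndarray) -> EntropyReport:
    """Normalized von Neumann entropy of a cell-type covariance matrix.

    The covariance is converted to a correlation matrix; its eigenvalues,
    divided by k so they form a distribution, enter the Shannon entropy
    (natural log, with 0 log 0 = 0), and the result is scaled by log(k) to
    land in [0, 1]. Identity correlation gives 1 (no covariance structure);
    a rank-1 correlation gives 0 (perfectly coupled cell types).
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if cov.ndim != 2 or cov.shape != (k, k) or k < 2:
        raise ValueError("entropy requires a square k x k matrix with k >= 2")
    if np.max(np.abs(cov - cov.T)) > 1e-8:
        raise ValueError("covariance must be symmetric")
    d = np.diag(cov)
    if np.any(d <= 0):
        raise ValueError(
            "covariance has a non-positive diagonal entry; correlation undefined"
        )
    sd = np.sqrt(d)
    corr = cov / np.outer(sd, sd)
    lam = np.linalg.eigvalsh(0.5 * (corr + corr.T))
    if lam[0] < -1e-8:
        raise ValueError("covariance is not positive semidefinite")
    lam = np.clip(lam, 0.0, None) / k
    nz = lam[lam > 0]
    raw = float(-(nz * np.log(nz)).sum())
    return EntropyReport(raw=raw, normalized=min(raw / np.log(k), 1.0), k=k)


def root_median_squared_error(truth: np.ndarray, estimate: np.ndarray) -> float:
    """sqrt(median((truth - estimate)^2)) — robust to a minority of outliers."""
    truth = np.asarray(truth, dtype=float).reshape(-1)
    estimate = np.asarray(estimate, dtype=float).reshape(-1)
    if truth.shape[0] != estimate.shape[0]:
        raise ValueError("truth and estimate must share length")
    if truth.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.median((truth - estimate) ** 2)))


def _two_sd_mask(x: np.ndarray, nsd: float = 2.0) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        return np.ones(x.shape[0], dtype=bool)
    return np.abs(x - x.mean()) <= nsd * sd


def delta_log10_p(
    true_z: np.ndarray,
    bulk_x: np.ndarray,
    proportions: ProportionMatrix,
    est_z: np.ndarray,
    log_transform: bool = True,
) -> float:
    """Information-beyond-bulk score for one (feature, cell type).

    Regresses the true cell-type levels on the bulk values, all proportion
    columns, and the estimated levels, and returns log10 p(bulk) - log10
    p(estimate) from two-sided t-tests (higher is better: the estimate
    explains truth that bulk cannot). Expression-scale inputs are
    log1p-transformed (after shifting to nonnegative if needed) and samples
    beyond 2 SD of the mean true level are dropped. A constant estimate is
    assigned p = 1, making the score non-positive.
    """
    true_z = np.asarray(true_z, dtype=float).reshape(-1)
    bulk_x = np.asarray(bulk_x, dtype=float).reshape(-1)
    est_z = np.asarray(est_z, dtype=float).reshape(-1)
    W = proportions.values
    n, k = W.shape
    if not (true_z.shape[0] == bulk_x.shape[0] == est_z.shape[0] == n):
        raise ValueError("all inputs must share the sample axis")
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 samples (n={n}, k={k})")

    def prep(v: np.ndarray) -> np.ndarray:
        if not log_transform:
            return v
        shifted = v - min(v.min(), 0.0)
        return np.log1p(shifted)

    t, b, e = prep(true_z), prep(bulk_x), prep(est_z)
    keep = _two_sd_mask(t)
    t, b, e, Wk = t[keep], b[keep], e[keep], W[keep]

    est_constant = np.std(e) == 0.0
    D = np.column_stack([np.ones(t.shape[0]), b, Wk, e])
    rank = np.linalg.matrix_rank(D)
    flagged = rank < D.shape[1]
    if flagged:
        logger.warning(
            "collinear regressors in delta_log10_p; using a regularized fit"
        )
        ridge = 1e-8 * np.eye(D.shape[1])
        ridge[0, 0] = 0.0
        H = D.T @ D + ridge
        coef = np.linalg.solve(H, D.T @ t)
        resid = t - D @ coef
        df = max(t.shape[0] - rank, 1)
        s2 = float(resid @ resid) / df
        cov = s2 * np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        tstat = coef / np.maximum(se, 1e-300)
        pvals = 2 * stats.t.sf(np.abs(tstat), df)
    else:
        res = sm.OLS(t, D).fit()
        pvals = res.pvalues
    p_bulk = float(np.clip(pvals[1], 1e-300, 1.0))
    p_est = 1.0 if est_constant else float(np.clip(pvals[-1], 1e-300, 1.0))
    return float(np.log10(p_bulk) - np.log10(p_est))


@dataclass
class MomentRecovery:
    """Across-feature correlations between fitted and gold-standard moments."""

    mean_correlation: np.ndarray  # (k,)
    variance_correlation: np.ndarray  # (k,)
    covariance_correlation: dict  # (a, b) -> r for a < b
    pooled_covariance_correlation: float
    cell_type_ids: list[str]


def moment_recovery(true_profiles: CellTensor, fit: ModelFit) -> MomentRecovery:
    """Score parameter recovery against trimmed empirical moments of the truth.

    Gold-standard per-feature moments are computed from the true cell-type
    profiles using only samples within 2 SD of the mean (per cell type;
    covariance uses the intersection of the pair's masks), then correlated
    with the fitted parameters across features via ``robust_correlation``.
    """
    n, m, k = true_profiles.shape
    if m < 10:
        raise ValueError("moment recovery needs at least 10 features")
    if fit.n_features != m:
        raise ValueError("fit and tensor disagree on the feature axis")
    gold_mu = np.empty((m, k))
    gold_var = np.empty((m, k))
    pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    gold_cov = np.empty((m, len(pairs)))
    for j in range(m):
        zj = true_profiles.values[:, j, :]
        masks = [_two_sd_mask(zj[:, h]) for h in range(k)]
        for h in range(k):
            v = zj[masks[h], h]
            gold_mu[j, h] = v.mean()
            gold_var[j, h] = v.var(ddof=1) if v.shape[0] > 1 else 0.0
        for idx, (a, b) in enumerate(pairs):
            both = masks[a] & masks[b]
            if both.sum() > 1:
                gold_cov[j, idx] = np.cov(zj[both, a], zj[both, b])[0, 1]
            else:
                gold_cov[j, idx] = 0.0
    fit_mu = np.array([p.mu for p in fit.params])
    fit_var = np.array([np.diag(p.sigma) for p in fit.params])
    fit_cov = np.array([[p.sigma[a, b] for a, b in pairs] for p in fit.params])
    mean_r = np.array(
        [robust_correlation(gold_mu[:, h], fit_mu[:, h]) for h in range(k)]
    )
    var_r = np.array(
        [robust_correlation(gold_var[:, h], fit_var[:, h]) for h in range(k)]
    )
    cov_r = {
        pairs[idx]: robust_correlation(gold_cov[:, idx], fit_cov[:, idx])
        for idx in range(len(pairs))
    }
    pooled = (
        robust_correlation(gold_cov.ravel(), fit_cov.ravel())
        if pairs
        else float("nan")
    )
    return MomentRecovery(
        mean_correlation=mean_r,
        variance_correlation=var_r,
        covariance_correlation=cov_r,
        pooled_covariance_correlation=pooled,
        cell_type_ids=list(true_profiles.cell_type_ids),
    )


def effect_beyond_composition(
    est_level: np.ndarray,
    composition: np.ndarray,
    status: np.ndarray,
) -> tuple[float, float]:
    """Standardized phenotype effect on estimated cell-type levels, adjusted
    for cell composition.

    The estimates are shifted to nonnegative (subtracting the minimum),
    log1p-transformed and standardized, then regressed on the composition and
    the binary status; the status coefficient and its two-sided p-value are
    returned. Constant estimates yield an effect of 0 (p = 1) — a method
    whose "estimates" merely reproduce composition will show no effect here.
    """
    est_level = np.asarray(est_level, dtype=float).reshape(-1)
    composition = np.asarray(composition, dtype=float).reshape(-1)
    status = np.asarray(status, dtype=float).reshape(-1)
    if not (est_level.shape[0] == composition.shape[0] == status.shape[0]):
        raise ValueError("all inputs must share the sample axis")
    classes = np.unique(status)
    if classes.shape[0] < 2:
        raise ValueError("status must contain both classes")
    y = np.log1p(est_level - est_level.min())
    sd = np.std(y)
    if sd == 0.0:
        return 0.0, 1.0
    y = (y - y.mean()) / sd
    D = np.column_stack([np.ones(y.shape[0]), composition, status])
    res = sm.OLS(y, D).fit()
    return float(res.params[2]), float(res.pvalues[2])
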