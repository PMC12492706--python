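"""Cell-type-level association testing and cross-dataset replication scoring.

Testing is "one-step": rather than regressing phenotypes on explicit tensor
point estimates, the phenotype enters the bulk-level model directly,

    X_ij = sum_h w_ih (mu_jh + delta_jh y_i + c1_i^T gamma_jh)
           + c2_i^T beta_j + noise,   Var[noise_i] = w_i^T Sigma_j w_i + tau_j^2,

and delta_jh is estimated by weighted (generalized) least squares with the
model-implied per-sample variances from a prior fit, so high-uncertainty
samples are down-weighted. The parametric mode derives p-values from
normal-theory t statistics; the asymptotic (distribution-free) mode keeps the
identical point estimates but uses a heteroskedasticity-robust sandwich
covariance. The joint (tissue-level) test is a Wald test of all k phenotype
coefficients, which reduces exactly to the marginal test at k = 1.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import statsmodels.api as sm

from .containers import (
    EMPTY_COVARIATES,
    AssociationResult,
    BulkMatrix,
    CovariateSet,
    DimensionError,
    ModelFit,
    ProportionMatrix,
    ReplicationSummary,
)
from .core import bulk_variance

logger = logging.getLogger("unico")

#: a cell type whose fitted level variance is at or below this is treated as
#: having no variation; its p-value is defined to be 1
ZERO_VARIANCE_TOL = 1e-12

_MODE_ALIASES = {
    "param": "parametric", "parametric": "parametric",
    "asymp": "asymptotic", "asymptotic": "asymptotic",
}


def _collinear_columns(D: np.ndarray, candidates: list[int]) -> set[int]:
    """Indices among ``candidates`` that lie in the span of the other columns."""
    out: set[int] = set()
    if np.linalg.matrix_rank(D) == D.shape[1]:
        return out
    for c in candidates:
        others = np.delete(D, c, axis=1)
        coef, *_ = np.linalg.lstsq(others, D[:, c], rcond=None)
        resid = D[:, c] - others @ coef
        scale = max(float(np.linalg.norm(D[:, c])), 1e-12)
        if np.linalg.norm(resid) / scale < 1e-8:
            out.add(c)
    return out


def _test_feature(
    x: np.ndarray,
    W: np.ndarray,
    y: np.ndarray,
    cov: CovariateSet,
    variance: np.ndarray,
    mask: np.ndarray,
    mode: str,
    zero_var: np.ndarray,
):
    n, k = W.shape
    blocks = [W, W * y[:, None]]
    for p in range(cov.p1):
        blocks.append(W * cov.cell_level[:, p][:, None])
    if cov.p2:
        blocks.append(cov.tissue_level)
    D = np.hstack(blocks)
    use = mask & np.isfinite(x)
    Du, xu = D[use], x[use]
    wts = 1.0 / np.maximum(variance[use], 1e-12)
    delta_cols = list(range(k, 2 * k))
    bad = _collinear_columns(Du, delta_cols)

    model = sm.WLS(xu, Du, weights=wts)
    res = model.fit()
    if mode == "asymptotic":
        infer = res.get_robustcov_results(cov_type="HC3", use_t=True)
    else:
        infer = res

    eff = np.asarray(res.params)[delta_cols]
    se = np.asarray(infer.bse)[delta_cols]
    stat = np.asarray(infer.tvalues)[delta_cols]
    pval = np.asarray(infer.pvalues)[delta_cols]
    for h in range(k):
        if zero_var[h] or (k + h) in bad:
            pval[h], stat[h], se[h] = 1.0, 0.0, np.inf
    good = [k + h for h in range(k) if not zero_var[h] and (k + h) not in bad]
    if not good:
        return eff, se, stat, pval, 0.0, 1.0
    R = np.zeros((len(good), D.shape[1]))
    for r, c in enumerate(good):
        R[r, c] = 1.0
    try:
        ftest = infer.f_test(R)
        joint_stat = float(np.squeeze(ftest.fvalue))
        joint_p = float(np.squeeze(ftest.pvalue))
    except Exception:  # pragma: no cover - singular-design fallback
        joint_stat, joint_p = 0.0, 1.0
    return eff, se, stat, pval, joint_stat, min(max(joint_p, 0.0), 1.0)


def test_marginal(
    fit: ModelFit,
    bulk: BulkMatrix,
    proportions: ProportionMatrix,
    phenotype: np.ndarray,
    covariates: CovariateSet | None = None,
    mode: str = "parametric",
) -> AssociationResult:
    """Per-feature, per-cell-type phenotype association tests.

    Returns effects, standard errors, t statistics and p-values for each
    (feature, cell type), plus the per-feature joint test. Samples masked as
    outliers during fitting are excluded; cell types whose fitted level
    variance is zero get p = 1.
    """
    mode = _MODE_ALIASES.get(mode)
    if mode is None:
        raise ValueError("mode must be 'parametric' or 'asymptotic'")
    cov = covariates or EMPTY_COVARIATES
    y = np.asarray(phenotype, dtype=float).reshape(-1)
    if y.shape[0] != bulk.n_samples:
        raise DimensionError(
            f"phenotype has {y.shape[0]} entries; bulk has {bulk.n_samples} samples"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if np.std(y) == 0.0:
        raise ValueError("phenotype is constant; nothing to test")
    if fit.n_features != bulk.n_features:
        raise DimensionError("fit does not cover the bulk feature axis")
    cov.check_samples(bulk.n_samples)

    m, k = bulk.n_features, proportions.n_cell_types
    eff = np.empty((m, k))
    se = np.empty((m, k))
    stat = np.empty((m, k))
    pval = np.empty((m, k))
    jstat = np.empty(m)
    jp = np.empty(m)
    W = proportions.values
    for j in range(m):
        p = fit.params[j]
        variance = bulk_variance(p, proportions)
        zero_var = np.diag(p.sigma) <= ZERO_VARIANCE_TOL
        (eff[j], se[j], stat[j], pval[j], jstat[j], jp[j]) = _test_feature(
            bulk.values[:, j], W, y, cov, variance,
            fit.outlier_mask[j], mode, zero_var,
        )
    return AssociationResult(
        effects=eff,
        standard_errors=se,
        statistics=stat,
        pvalues=np.clip(pval, 0.0, 1.0),
        joint_statistics=jstat,
        joint_pvalues=np.clip(jp, 0.0, 1.0),
        mode=mode,
        feature_ids=bulk.feature_ids,
        cell_type_ids=proportions.cell_type_ids,
    )


def test_joint(
    fit: ModelFit,
    bulk: BulkMatrix,
    proportions: ProportionMatrix,
    phenotype: np.ndarray,
    covariates: CovariateSet | None = None,
    mode: str = "parametric",
) -> np.ndarray:
    """Per-feature joint (tissue-level) p-values: Wald test of all k
    phenotype coefficients on the same estimating equations."""
    return test_marginal(
        fit, bulk, proportions, phenotype, covariates, mode
    ).joint_pvalues


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal sum is zero."""
    for v in (tp, fp, tn, fn):
        if v < 0 or int(v) != v:
            raise ValueError("confusion counts must be nonnegative integers")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def f1_score(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else float(2 * tp / denom)


def _extract(result: AssociationResult, target):
    if target in ("joint", "tissue"):
        return result.joint_pvalues, None
    if isinstance(target, str):
        if target not in result.cell_type_ids:
            raise ValueError(f"unknown cell type {target!r}")
        h = result.cell_type_ids.index(target)
    else:
        h = int(target)
    return result.pvalues[:, h], result.effects[:, h]


def replication_consistency(
    discovery: AssociationResult,
    validation: AssociationResult,
    target="joint",
    alpha: float = 0.05,
) -> ReplicationSummary:
    """Score how well discovery hits replicate in an independent validation.

    A feature is a discovery hit if its discovery p-value passes Bonferroni
    over all tested features. Hits are true positives when they pass
    Bonferroni over the number of hits in the validation data with a
    consistent effect direction, false negatives otherwise. Features with
    discovery p > 0.95 serve as negative controls: those significant in
    validation under Bonferroni over the number of negative controls are
    false positives, the rest true negatives. Direction consistency applies
    to marginal (per-cell-type) results; the joint test carries no single
    effect sign. ``target`` is a cell-type id/index or ``"joint"``.
    """
    shared = [f for f in discovery.feature_ids if f in set(validation.feature_ids)]
    if len(shared) < len(discovery.feature_ids) or len(shared) < len(
        validation.feature_ids
    ):
        logger.warning(
            "feature sets differ; intersecting to %d shared features", len(shared)
        )
    if not shared:
        raise ValueError("discovery and validation share no features")
    di = [discovery.feature_ids.index(f) for f in shared]
    vi = [validation.feature_ids.index(f) for f in shared]
    p_d, e_d = _extract(discovery, target)
    p_v, e_v = _extract(validation, target)
    p_d, p_v = p_d[di], p_v[vi]
    if e_d is not None:
        e_d, e_v = e_d[di], e_v[vi]

    m = len(shared)
    thr_d = alpha / m
    hits = p_d <= thr_d
    n_hits = int(hits.sum())
    thr_v = alpha / max(n_hits, 1)
    replicated = hits & (p_v <= thr_v)
    if e_d is not None:
        replicated &= np.sign(e_d) == np.sign(e_v)
    tp = int(replicated.sum())
    fn = n_hits - tp

    controls = p_d > 0.95
    n_ctrl = int(controls.sum())
    thr_ctrl = alpha / max(n_ctrl, 1)
    fp = int((controls & (p_v <= thr_ctrl)).sum())
    tn = n_ctrl - fp

    undefined = n_hits == 0
    return ReplicationSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        mcc=0.0 if undefined else mcc(tp, fp, tn, fn),
        f1=f1_score(tp, fp, fn),
        discovery_threshold=thr_d,
        validation_threshold=thr_v,
        negative_control_threshold=thr_ctrl,
        undefined_mcc=undefined,
    )
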