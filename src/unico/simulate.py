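"""Synthetic-data generators: the package's full test bed.

Two complementary constructions are provided. ``simulate_parametric`` draws
cell-type levels from the generative model itself (multivariate levels with
per-feature mean vector, cell-type covariance of controllable entropy, and
i.i.d. measurement noise), which makes closed-form oracles exact.
``simulate_pseudobulk`` emulates the resampling construction used with real
single-cell data: each synthetic sample pairs the full cell-type profile of
one randomly drawn donor with the proportions of another, and the bulk value
is the exact weighted combination — no added noise, truth tensor recorded.

Defaults aim for realistic pseudo-bulk expression on a linear scale: mean
cell-type levels uniform on [0, 10], per-cell-type standard deviations
coupled to the means through a per-feature biological coefficient of
variation drawn from [0.1, 0.3] (expression variance grows with expression
level across genes), technical noise variance uniform on [0.01, 0.1], and
Dirichlet proportions with a decreasing concentration vector
(10, 5, 3, 2, 1, ...) mimicking the abundance skew of real tissues.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .containers import (
    BulkMatrix,
    CellTensor,
    FeatureParams,
    ProportionMatrix,
    SimulationTruth,
)
from .evaluation import von_neumann_entropy

logger = logging.getLogger("unico")

DEFAULT_MEAN_RANGE = (0.0, 10.0)
DEFAULT_SCALE_RANGE = (0.5, 2.0)
DEFAULT_CV_RANGE = (0.1, 0.3)
DEFAULT_TAU2_RANGE = (0.01, 0.1)
DEFAULT_ENTROPY_RANGE = (0.2, 0.95)


def default_concentration(k: int) -> np.ndarray:
    """Decreasing Dirichlet concentration (10, 5, 3, 2, 1, then halving)."""
    base = [10.0, 5.0, 3.0, 2.0, 1.0]
    while len(base) < k:
        base.append(base[-1] / 2.0)
    return np.array(base[:k])


def make_covariance(
    k: int,
    target_entropy: float,
    scale_range: tuple[float, float] = DEFAULT_SCALE_RANGE,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """PSD covariance whose correlation matrix has a prescribed normalized
    von Neumann entropy (within 0.05).

    The correlation part is a convex combination ``(1 - t) R1 + t I`` of a
    random rank-1 (+-1) correlation and the identity; ``t`` is found by
    bisection since entropy increases monotonically from 0 (rank-1) to 1
    (identity). Per-cell-type variances are drawn from ``scale_range``.
    """
    if k < 2:
        raise ValueError("make_covariance requires k >= 2")
    if not 0.0 <= target_entropy <= 1.0:
        raise ValueError("target_entropy must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    signs = rng.choice([-1.0, 1.0], size=k)
    rank1 = np.outer(signs, signs)
    eye = np.eye(k)

    def corr_at(t: float) -> np.ndarray:
        return (1.0 - t) * rank1 + t * eye

    def entropy_at(t: float) -> float:
        return von_neumann_entropy(corr_at(t)).normalized

    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if entropy_at(mid) < target_entropy:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    achieved = entropy_at(t)
    if abs(achieved - target_entropy) > 0.05:
        logger.warning(
            "entropy target %.3f unreachable; nearest achievable %.3f",
            target_entropy, achieved,
        )
    corr = corr_at(t)
    sd = np.sqrt(rng.uniform(*scale_range, size=k))
    return corr * np.outer(sd, sd)


def _draw_sigma(
    covariance_spec, k: int, rng: np.random.Generator, mu: np.ndarray
) -> np.ndarray:
    """Resolve a covariance specification into one k x k PSD draw.

    The default couples per-cell-type standard deviations to the mean levels
    through a per-feature biological coefficient of variation (``cv_range``);
    passing ``scale_range`` in the dict switches to absolute variances drawn
    uniformly from that range. A fixed matrix or a callable ``(rng, k) ->
    Sigma`` may be given instead.
    """
    if covariance_spec is None:
        covariance_spec = {}
    if callable(covariance_spec):
        return np.asarray(covariance_spec(rng, k), dtype=float)
    if isinstance(covariance_spec, np.ndarray):
        if covariance_spec.shape != (k, k):
            raise ValueError(
                f"fixed covariance has shape {covariance_spec.shape}; "
                f"expected ({k}, {k})"
            )
        return covariance_spec.copy()
    if isinstance(covariance_spec, dict):
        te = covariance_spec.get("target_entropy", DEFAULT_ENTROPY_RANGE)
        target = float(te) if np.isscalar(te) else float(rng.uniform(te[0], te[1]))
        if "scale_range" in covariance_spec:
            scale = covariance_spec["scale_range"]
            if k == 1:
                return np.array([[rng.uniform(*scale)]])
            return make_covariance(k, target, scale_range=scale, seed=rng)
        cv_range = covariance_spec.get("cv_range", DEFAULT_CV_RANGE)
        cv = rng.uniform(*cv_range)
        sd = cv * (mu + 0.5)
        if k == 1:
            return np.array([[sd[0] ** 2]])
        corr = make_covariance(k, target, scale_range=(1.0, 1.0), seed=rng)
        return corr * np.outer(sd, sd)
    raise ValueError("infeasible covariance_spec: expected dict, array or callable")


def _lognormal_noise(
    sigma: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean multivariate log-normal fluctuations moment-matched to
    ``sigma`` (approximately, for strongly negative correlations)."""
    k = sigma.shape[0]
    sd = np.sqrt(np.clip(np.diag(sigma), 1e-12, None))
    corr = sigma / np.outer(sd, sd)
    e = np.e
    rho = np.log(np.clip(1.0 + corr * (e - 1.0), 1e-6, None))
    evals, evecs = np.linalg.eigh(0.5 * (rho + rho.T))
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    g = rng.standard_normal((n, k)) @ L.T
    raw = np.exp(g) - np.exp(0.5)
    return raw / np.sqrt(e * (e - 1.0)) * sd


def simulate_parametric(
    n: int,
    m: int,
    k: int,
    mean_range: tuple[float, float] = DEFAULT_MEAN_RANGE,
    covariance_spec=None,
    tau2_range: tuple[float, float] = DEFAULT_TAU2_RANGE,
    effect_spec: dict | None = None,
    seed: int = 0,
    proportion_concentration: Sequence[float] | None = None,
    truncate_nonneg: bool = False,
    distribution: str = "normal",
) -> SimulationTruth:
    """Draw a full synthetic study from the generative model.

    Per feature: ``mu ~ U(mean_range)`` (componentwise, nonnegative for the
    default range), ``Sigma`` from ``covariance_spec`` (default: random
    entropy in [0.2, 0.95], standard deviations coupled to the means via a
    per-feature CV in [0.1, 0.3]), ``tau^2 ~ U(tau2_range)``. Cell-type levels are multivariate normal (or a
    moment-matched log-normal with ``distribution='lognormal'``, to probe
    robustness to skew); bulk is the proportion-weighted combination plus
    N(0, tau^2) noise. ``effect_spec={'cell_types': [...], 'effect_size': d,
    'binary': False}`` adds ``d * phenotype`` to the targeted cell types'
    levels. Negative levels are kept by default (the model is unconstrained);
    ``truncate_nonneg`` clips them at 0, which biases the recorded moments
    and is therefore flagged with a warning.
    """
    if min(n, m, k) < 1:
        raise ValueError("n, m, k must all be >= 1")
    if distribution not in ("normal", "lognormal"):
        raise ValueError("distribution must be 'normal' or 'lognormal'")
    rng = np.random.default_rng(seed)
    conc = (
        default_concentration(k)
        if proportion_concentration is None
        else np.asarray(proportion_concentration, dtype=float)
    )
    W = rng.dirichlet(conc, size=n)

    phenotype = None
    effect = np.zeros(k)
    if effect_spec is not None:
        if effect_spec.get("binary", False):
            phenotype = rng.integers(0, 2, size=n).astype(float)
        else:
            phenotype = rng.standard_normal(n)
        effect = np.zeros(k)
        effect[list(effect_spec.get("cell_types", [0]))] = float(
            effect_spec.get("effect_size", 0.5)
        )

    params: list[FeatureParams] = []
    Z = np.empty((n, m, k))
    X = np.empty((n, m))
    for j in range(m):
        mu = rng.uniform(mean_range[0], mean_range[1], size=k)
        sigma = _draw_sigma(covariance_spec, k, rng, mu)
        tau2 = float(rng.uniform(*tau2_range))
        if distribution == "normal":
            evals, evecs = np.linalg.eigh(sigma)
            L = evecs * np.sqrt(np.clip(evals, 0.0, None))
            eps = rng.standard_normal((n, k)) @ L.T
        else:
            eps = _lognormal_noise(sigma, n, rng)
        z = mu + eps
        if phenotype is not None:
            z = z + phenotype[:, None] * effect
        if truncate_nonneg:
            z = np.clip(z, 0.0, None)
        noise = rng.normal(0.0, np.sqrt(tau2), size=n)
        X[:, j] = np.einsum("ih,ih->i", W, z) + noise
        Z[:, j, :] = z
        params.append(FeatureParams(mu, sigma, tau2))
    if truncate_nonneg:
        logger.warning(
            "cell-type levels truncated at 0; recorded (mu, Sigma) no longer "
            "match the realized moments"
        )
    sample_ids = [f"sample{i}" for i in range(n)]
    feature_ids = [f"feature{j}" for j in range(m)]
    cell_ids = [f"cell_type{h}" for h in range(k)]
    return SimulationTruth(
        bulk=BulkMatrix(X, sample_ids, feature_ids),
        proportions=ProportionMatrix(W, sample_ids, cell_ids),
        tensor=CellTensor(Z, sample_ids, feature_ids, cell_ids),
        params=params,
        phenotype=phenotype,
        seed=seed,
    )


def simulate_pseudobulk(
    profile_pool: CellTensor,
    proportion_pool: ProportionMatrix,
    n_out: int,
    seed: int = 0,
) -> SimulationTruth:
    """Resampling pseudo-bulk: pair profile donors with proportion donors.

    Each output sample draws (with replacement) the complete cell-type level
    profile of one random pool sample and, independently, the proportions of
    another; the bulk value is the exact weighted combination. The recorded
    per-feature parameters are the empirical mean/covariance of the profile
    pool with tau^2 = 0.
    """
    if profile_pool.shape[0] == 0 or proportion_pool.n_samples == 0:
        raise ValueError("pools must be non-empty")
    if profile_pool.cell_type_ids != proportion_pool.cell_type_ids:
        raise ValueError(
            "profile and proportion pools disagree on the cell-type axis"
        )
    rng = np.random.default_rng(seed)
    iz = rng.integers(0, profile_pool.shape[0], size=n_out)
    iw = rng.integers(0, proportion_pool.n_samples, size=n_out)
    Z = profile_pool.values[iz]
    W = proportion_pool.values[iw]
    W = W / W.sum(axis=1, keepdims=True)
    X = np.einsum("ih,ijh->ij", W, Z)
    m = profile_pool.shape[1]
    params = []
    pool = profile_pool.values
    for j in range(m):
        mu = pool[:, j, :].mean(axis=0)
        sigma = np.cov(pool[:, j, :], rowvar=False) if pool.shape[0] > 1 \
            else np.zeros((pool.shape[2],) * 2)
        sigma = np.atleast_2d(sigma)
        params.append(FeatureParams(mu, 0.5 * (sigma + sigma.T), 0.0))
    sample_ids = [f"mix{i}" for i in range(n_out)]
    return SimulationTruth(
        bulk=BulkMatrix(X, sample_ids, list(profile_pool.feature_ids)),
        proportions=ProportionMatrix(
            W, sample_ids, list(proportion_pool.cell_type_ids)
        ),
        tensor=CellTensor(
            Z, sample_ids, list(profile_pool.feature_ids),
            list(profile_pool.cell_type_ids),
        ),
        params=params,
        phenotype=None,
        seed=seed,
    )


def add_proportion_noise(
    proportions: ProportionMatrix, level: float, seed: int = 0
) -> ProportionMatrix:
    """Perturb proportions with logistic-normal noise of SD ``level``.

    Noise is added on the log scale and rows are re-projected to the simplex
    by renormalization; ``level=0`` returns an unchanged copy.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return ProportionMatrix(
            proportions.values.copy(),
            list(proportions.sample_ids),
            list(proportions.cell_type_ids),
        )
    rng = np.random.default_rng(seed)
    logw = np.log(np.clip(proportions.values, 1e-12, None))
    logw = logw + rng.normal(0.0, level, size=logw.shape)
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    w = w / w.sum(axis=1, keepdims=True)
    return ProportionMatrix(
        w, list(proportions.sample_ids), list(proportions.cell_type_ids)
    )
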