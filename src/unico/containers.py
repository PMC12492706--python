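"""Typed containers shared across the package.

Conventions: samples are rows everywhere; the cell-type-level tensor is
indexed ``(sample, feature, cell_type)``. All containers validate on
construction and hold plain numpy arrays plus ordered string labels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("unico")

#: tolerance for symmetry of a fitted covariance matrix
SYMMETRY_TOL = 1e-10
#: most negative eigenvalue tolerated in a "positive semidefinite" matrix
PSD_TOL = -1e-8
#: proportion rows whose sum deviates from 1 by more than this are rejected
PROPORTION_SUM_TOL = 1e-2


class DimensionError(ValueError):
    """Raised when two inputs disagree on a shared axis; names the axis."""


def _check_finite(values: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        raise ValueError(
            f"{name} contains {len(bad)} non-finite entries; first at index "
            f"{tuple(bad[0])}"
        )


def _labels(ids, n: int, name: str) -> list[str]:
    if ids is None:
        return [f"{name}{i}" for i in range(n)]
    ids = [str(x) for x in ids]
    if len(ids) != n:
        raise DimensionError(
            f"{name} axis has {n} entries but {len(ids)} labels were given"
        )
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate labels on the {name} axis")
    return ids


@dataclass
class BulkMatrix:
    """Observed bulk mixtures x_ij, samples x features, in linear data units."""

    values: np.ndarray
    sample_ids: list[str] | None = None
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("bulk values must be a 2D samples x features matrix")
        _check_finite(self.values, "bulk matrix")
        self.sample_ids = _labels(self.sample_ids, self.values.shape[0], "sample")
        self.feature_ids = _labels(self.feature_ids, self.values.shape[1], "feature")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ProportionMatrix:
    """Per-sample cell-type proportions w_i on the k-simplex."""

    values: np.ndarray
    sample_ids: list[str] | None = None
    cell_type_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("proportions must be a 2D samples x cell-types matrix")
        _check_finite(self.values, "proportion matrix")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("proportions must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        off = np.abs(sums - 1.0)
        if np.any(off > PROPORTION_SUM_TOL):
            i = int(np.argmax(off))
            raise ValueError(
                f"proportion row {i} sums to {sums[i]:.6g}; deviation exceeds "
                f"{PROPORTION_SUM_TOL}"
            )
        if np.any(off > 1e-6):
            logger.warning(
                "renormalizing %d proportion rows whose sums deviate from 1 "
                "by up to %.3g", int(np.sum(off > 1e-6)), float(off.max()),
            )
            self.values = self.values / sums[:, None]
        self.values = np.clip(self.values, 0.0, 1.0)
        self.sample_ids = _labels(self.sample_ids, self.values.shape[0], "sample")
        self.cell_type_ids = _labels(
            self.cell_type_ids, self.values.shape[1], "cell_type"
        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateSet:
    """Covariates with cell-type-specific effects (``cell_level``, n x p1) and
    global tissue-level covariates such as batch surrogates (``tissue_level``,
    n x p2). Either block may be absent."""

    cell_level: np.ndarray | None = None
    tissue_level: np.ndarray | None = None
    cell_level_names: list[str] | None = None
    tissue_level_names: list[str] | None = None

    def __post_init__(self) -> None:
        for attr in ("cell_level", "tissue_level"):
            v = getattr(self, attr)
            if v is not None:
                v = np.atleast_2d(np.asarray(v, dtype=float))
                if v.shape[1] == 0:
                    v = None
                else:
                    _check_finite(v, attr)
                setattr(self, attr, v)
        if self.cell_level is not None:
            self.cell_level_names = _labels(
                self.cell_level_names, self.cell_level.shape[1], "cell_covariate"
            )
        if self.tissue_level is not None:
            self.tissue_level_names = _labels(
                self.tissue_level_names, self.tissue_level.shape[1], "tissue_covariate"
            )

    @property
    def p1(self) -> int:
        return 0 if self.cell_level is None else self.cell_level.shape[1]

    @property
    def p2(self) -> int:
        return 0 if self.tissue_level is None else self.tissue_level.shape[1]

    def check_samples(self, n: int) -> None:
        for attr in ("cell_level", "tissue_level"):
            v = getattr(self, attr)
            if v is not None and v.shape[0] != n:
                raise DimensionError(
                    f"{attr} covariates have {v.shape[0]} rows; expected {n} samples"
                )


EMPTY_COVARIATES = CovariateSet()


@dataclass
class FeatureParams:
    """Fitted model for one feature: mean cell-type levels ``mu`` (data
    units), cell-type variance-covariance ``sigma`` (squared data units),
    measurement-noise variance ``tau2``, and optional covariate effects
    ``gamma`` (k x p1, cell-type-level) and ``beta`` (p2, tissue-level)."""

    mu: np.ndarray
    sigma: np.ndarray
    tau2: float
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(-1)
        self.sigma = np.asarray(self.sigma, dtype=float)
        k = self.mu.shape[0]
        if self.sigma.shape != (k, k):
            raise DimensionError(
                f"sigma has shape {self.sigma.shape}; expected ({k}, {k})"
            )
        _check_finite(self.mu, "mu")
        _check_finite(self.sigma, "sigma")
        if np.max(np.abs(self.sigma - self.sigma.T)) > SYMMETRY_TOL:
            raise ValueError("sigma is not symmetric")
        if k > 0 and np.linalg.eigvalsh(self.sigma)[0] < PSD_TOL:
            raise ValueError("sigma is not positive semidefinite")
        self.tau2 = float(self.tau2)
        if not np.isfinite(self.tau2) or self.tau2 < 0:
            raise ValueError("tau2 must be a finite nonnegative scalar")
        if self.gamma is not None:
            self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
            if self.gamma.shape[0] != k:
                raise DimensionError("gamma must have one row per cell type")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float).reshape(-1)

    @property
    def k(self) -> int:
        return self.mu.shape[0]


@dataclass
class FitConfig:
    """Knobs of the iterative moment-matching fit; defaults follow the
    method's recommended practice (2 mean iterations, 3 variance iterations,
    2-SD outlier masking, small L2 penalty on the second-moment solve)."""

    mean_iterations: int = 2
    var_iterations: int = 3
    outlier_sd: float = 2.0
    l2_penalty: float = 1e-4  # relative: multiplied by (feature variance)^2
    nonneg_means: bool = True
    weight_floor: float = 1e-4
    weight_cap: float = 1e4
    tol: float = 1e-8
    max_evals: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_iterations < 1 or self.var_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be nonnegative")
        if self.weight_floor <= 0 or self.weight_cap <= 0:
            raise ValueError("weight bounds must be positive")


@dataclass
class ModelFit:
    """Per-feature fitted parameters plus the fitting state needed downstream:
    the final sample weights (diagonal of the moment-condition weight matrix),
    the 2-SD outlier masks (True = sample used), and diagnostics."""

    params: list[FeatureParams]
    sample_weights: np.ndarray  # (m, n)
    outlier_mask: np.ndarray  # (m, n) boolean
    config: FitConfig
    diagnostics: list[dict] = field(default_factory=list)
    feature_ids: list[str] | None = None
    sample_ids: list[str] | None = None
    cell_type_ids: list[str] | None = None

    def __post_init__(self) -> None:
        m = len(self.params)
        self.sample_weights = np.asarray(self.sample_weights, dtype=float)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.sample_weights.shape != self.outlier_mask.shape:
            raise DimensionError("sample_weights and outlier_mask shapes differ")
        if self.sample_weights.shape[0] != m:
            raise DimensionError("one weight vector per feature is required")
        if np.any(self.sample_weights < 0):
            raise ValueError("sample weights must be nonnegative")
        self.feature_ids = _labels(self.feature_ids, m, "feature")
        n = self.sample_weights.shape[1]
        self.sample_ids = _labels(self.sample_ids, n, "sample")
        k = self.params[0].k if m else 0
        self.cell_type_ids = _labels(self.cell_type_ids, k, "cell_type")

    @property
    def n_features(self) -> int:
        return len(self.params)

    def flagged(self) -> np.ndarray:
        """Boolean vector marking features whose fit was flagged as unreliable."""
        return np.array([bool(d.get("flagged", False)) for d in self.diagnostics])


@dataclass
class CellTensor:
    """Cell-type-level profiles z_ijh, indexed (sample, feature, cell_type)."""

    values: np.ndarray
    sample_ids: list[str] | None = None
    feature_ids: list[str] | None = None
    cell_type_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError(
                "tensor values must be 3D (sample, feature, cell_type)"
            )
        _check_finite(self.values, "cell tensor")
        n, m, k = self.values.shape
        self.sample_ids = _labels(self.sample_ids, n, "sample")
        self.feature_ids = _labels(self.feature_ids, m, "feature")
        self.cell_type_ids = _labels(self.cell_type_ids, k, "cell_type")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class MomentResiduals:
    """Sample-specific first/second moment-condition residuals for one feature:
    ``first_i = E[X_ij] - x_ij`` and
    ``second_i = Var[X_ij] - (x_ij - E[X_ij])^2``."""

    first: np.ndarray
    second: np.ndarray

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=float).reshape(-1)
        self.second = np.asarray(self.second, dtype=float).reshape(-1)
        if self.first.shape != self.second.shape:
            raise DimensionError("moment residual vectors must share length")
        _check_finite(self.first, "first-moment residuals")
        _check_finite(self.second, "second-moment residuals")


@dataclass
class AssociationResult:
    """Per feature x cell type phenotype effects and p-values, plus the
    per-feature joint (tissue-level) test."""

    effects: np.ndarray  # (m, k) data units per phenotype unit
    standard_errors: np.ndarray  # (m, k)
    statistics: np.ndarray  # (m, k)
    pvalues: np.ndarray  # (m, k)
    joint_statistics: np.ndarray  # (m,)
    joint_pvalues: np.ndarray  # (m,)
    mode: str  # "parametric" | "asymptotic"
    feature_ids: list[str] | None = None
    cell_type_ids: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("effects", "standard_errors", "statistics", "pvalues"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.joint_statistics = np.asarray(self.joint_statistics, dtype=float)
        self.joint_pvalues = np.asarray(self.joint_pvalues, dtype=float)
        m, k = self.effects.shape
        if self.pvalues.shape != (m, k) or self.joint_pvalues.shape != (m,):
            raise DimensionError("association result arrays disagree on shape")
        for p in (self.pvalues, self.joint_pvalues):
            finite = p[np.isfinite(p)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError("p-values must lie in [0, 1]")
        if self.mode not in ("parametric", "asymptotic"):
            raise ValueError("mode must be 'parametric' or 'asymptotic'")
        self.feature_ids = _labels(self.feature_ids, m, "feature")
        self.cell_type_ids = _labels(self.cell_type_ids, k, "cell_type")


@dataclass
class ReplicationSummary:
    """Discovery/validation replication counts and consistency scores."""

    tp: int
    fp: int
    tn: int
    fn: int
    mcc: float
    f1: float
    discovery_threshold: float
    validation_threshold: float
    negative_control_threshold: float
    undefined_mcc: bool = False

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer")
            setattr(self, name, int(v))
        if not -1 - 1e-12 <= self.mcc <= 1 + 1e-12:
            raise ValueError("mcc must lie in [-1, 1]")
        if not -1e-12 <= self.f1 <= 1 + 1e-12:
            raise ValueError("f1 must lie in [0, 1]")


@dataclass
class EntropyReport:
    """von Neumann entropy of a cell-type covariance structure."""

    raw: float  # nats
    normalized: float  # raw / log(k), in [0, 1]
    k: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("entropy is defined for k >= 2 cell types")
        if not -1e-9 <= self.normalized <= 1 + 1e-9:
            raise ValueError("normalized entropy must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Everything a simulation knows: the observable inputs (bulk,
    proportions) and the hidden ground truth (tensor, per-feature parameters,
    optional phenotype), reproducible from ``seed``."""

    bulk: BulkMatrix
    proportions: ProportionMatrix
    tensor: CellTensor
    params: list[FeatureParams]
    phenotype: np.ndarray | None
    seed: int
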