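"""Readers and writers for matrices, tensors and fitted parameters.

Text formats are TSV/CSV with a header row of feature / cell-type labels and
the first column holding sample IDs; floats are written with 17 significant
digits so text round trips are lossless at double precision. Tensors and
fitted parameters additionally have a binary named-axis container (NPZ) whose
round trip is bit-exact, plus a per-cell-type TSV export with a JSON manifest.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BulkMatrix,
    CellTensor,
    CovariateSet,
    FeatureParams,
    FitConfig,
    ModelFit,
    ProportionMatrix,
)

logger = logging.getLogger("unico")

FLOAT_FMT = "%.17g"
KINDS = ("bulk", "proportions", "covariates", "phenotype")


def _jsonable(obj):
    """Coerce numpy scalars so diagnostics serialize cleanly."""
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def _read_frame(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0, float_precision="round_trip"
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column label {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell at sample {df.index[r]!r}, column "
            f"{df.columns[c]!r} in {path}"
        )
    if numeric.isna().any().any():
        coords = [
            f"({df.index[r]}, {df.columns[c]})"
            for r, c in np.argwhere(numeric.isna().values)[:5]
        ]
        raise ValueError(f"missing values in {path} at {', '.join(coords)} ...")
    return numeric


def read_matrix(path, kind: str):
    """Read a labelled matrix; ``kind`` selects validation and return type.

    bulk -> BulkMatrix; proportions -> ProportionMatrix (rows renormalized
    with a warning when the sum deviates from 1 by less than 1e-2, rejected
    beyond); covariates -> (values, sample_ids, column_names); phenotype ->
    (vector, sample_ids), taking the first column.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_frame(path)
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if kind == "bulk":
        return BulkMatrix(df.values, ids, cols)
    if kind == "proportions":
        return ProportionMatrix(df.values, ids, cols)
    if kind == "covariates":
        return df.values.astype(float), ids, cols
    return df.values[:, 0].astype(float), ids


def write_matrix(values, sample_ids, column_ids, path) -> None:
    path = Path(path)
    df = pd.DataFrame(np.asarray(values), index=sample_ids, columns=column_ids)
    df.to_csv(path, sep=_sep(path), float_format=FLOAT_FMT, index_label="sample")


# ---------------------------------------------------------------------------
# tensor containers

def write_tensor(tensor: CellTensor, path) -> None:
    """Binary named-axis container; round trips bit-exactly."""
    np.savez(
        Path(path),
        values=tensor.values,
        sample_ids=np.array(tensor.sample_ids, dtype=str),
        feature_ids=np.array(tensor.feature_ids, dtype=str),
        cell_type_ids=np.array(tensor.cell_type_ids, dtype=str),
    )


def read_tensor(path) -> CellTensor:
    with np.load(Path(path), allow_pickle=False) as npz:
        required = {"values", "sample_ids", "feature_ids", "cell_type_ids"}
        if not required <= set(npz.files):
            raise ValueError(
                f"tensor container {path} is missing {required - set(npz.files)}"
            )
        return CellTensor(
            npz["values"],
            list(npz["sample_ids"]),
            list(npz["feature_ids"]),
            list(npz["cell_type_ids"]),
        )


def export_tensor_tsv(tensor: CellTensor, directory) -> None:
    """One samples-x-features TSV per cell type plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for h, ct in enumerate(tensor.cell_type_ids):
        fname = f"tensor_{h}.tsv"
        write_matrix(
            tensor.values[:, :, h],
            tensor.sample_ids,
            tensor.feature_ids,
            directory / fname,
        )
        files[ct] = fname
    manifest = {
        "cell_type_ids": tensor.cell_type_ids,
        "files": files,
        "n_samples": tensor.shape[0],
        "n_features": tensor.shape[1],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def import_tensor_tsv(directory) -> CellTensor:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    planes = []
    sample_ids = feature_ids = None
    for ct in manifest["cell_type_ids"]:
        fpath = directory / manifest["files"][ct]
        if not fpath.exists():
            raise ValueError(
                f"manifest lists cell type {ct!r} but {fpath.name} is missing"
            )
        df = _read_frame(fpath)
        planes.append(df.values)
        sample_ids = [str(i) for i in df.index]
        feature_ids = [str(c) for c in df.columns]
    values = (
        np.stack(planes, axis=2)
        if planes
        else np.empty((manifest["n_samples"], manifest["n_features"], 0))
    )
    return CellTensor(values, sample_ids, feature_ids, manifest["cell_type_ids"])


# ---------------------------------------------------------------------------
# fitted parameters

def write_fit(fit: ModelFit, path, summary_path=None) -> None:
    """Lossless binary serialization plus an optional JSON summary."""
    m = fit.n_features
    k = fit.params[0].k if m else 0
    arrays = {
        "mu": np.array([p.mu for p in fit.params]).reshape(m, k),
        "sigma": np.array([p.sigma for p in fit.params]).reshape(m, k, k),
        "tau2": np.array([p.tau2 for p in fit.params]),
        "sample_weights": fit.sample_weights,
        "outlier_mask": fit.outlier_mask,
        "feature_ids": np.array(fit.feature_ids, dtype=str),
        "sample_ids": np.array(fit.sample_ids, dtype=str),
        "cell_type_ids": np.array(fit.cell_type_ids, dtype=str),
        "config_json": np.array(
            json.dumps(dataclasses.asdict(fit.config), default=_jsonable)
        ),
        "diagnostics_json": np.array(
            json.dumps(fit.diagnostics, default=_jsonable)
        ),
    }
    if m and fit.params[0].gamma is not None:
        arrays["gamma"] = np.array([p.gamma for p in fit.params])
    if m and fit.params[0].beta is not None:
        arrays["beta"] = np.array([p.beta for p in fit.params])
    np.savez(Path(path), **arrays)
    if summary_path is not None:
        summary = {
            "n_features": m,
            "n_samples": len(fit.sample_ids),
            "cell_type_ids": fit.cell_type_ids,
            "config": dataclasses.asdict(fit.config),
            "n_flagged": int(fit.flagged().sum()),
            "mean_tau2": float(np.mean([p.tau2 for p in fit.params])) if m else 0.0,
        }
        Path(summary_path).write_text(json.dumps(summary, indent=1))


def read_fit(path) -> ModelFit:
    with np.load(Path(path), allow_pickle=False) as npz:
        mu, sigma, tau2 = npz["mu"], npz["sigma"], npz["tau2"]
        gamma = npz["gamma"] if "gamma" in npz.files else None
        beta = npz["beta"] if "beta" in npz.files else None
        params = [
            FeatureParams(
                mu[j], sigma[j], float(tau2[j]),
                gamma=None if gamma is None else gamma[j],
                beta=None if beta is None else beta[j],
            )
            for j in range(mu.shape[0])
        ]
        config = FitConfig(**json.loads(str(npz["config_json"])))
        diagnostics = json.loads(str(npz["diagnostics_json"]))
        return ModelFit(
            params=params,
            sample_weights=npz["sample_weights"],
            outlier_mask=npz["outlier_mask"],
            config=config,
            diagnostics=diagnostics,
            feature_ids=list(npz["feature_ids"]),
            sample_ids=list(npz["sample_ids"]),
            cell_type_ids=list(npz["cell_type_ids"]),
        )


# ---------------------------------------------------------------------------
# association results

def write_association(result, path) -> None:
    rows = []
    m, k = result.effects.shape
    for j in range(m):
        for h in range(k):
            rows.append(
                {
                    "feature": result.feature_ids[j],
                    "cell_type": result.cell_type_ids[h],
                    "effect": result.effects[j, h],
                    "se": result.standard_errors[j, h],
                    "statistic": result.statistics[j, h],
                    "pvalue": result.pvalues[j, h],
                    "joint_statistic": result.joint_statistics[j],
                    "joint_pvalue": result.joint_pvalues[j],
                    "mode": result.mode,
                }
            )
    pd.DataFrame(rows).to_csv(
        Path(path), sep=_sep(Path(path)), float_format=FLOAT_FMT, index=False
    )


def read_association(path):
    from .containers import AssociationResult

    df = pd.read_csv(
        Path(path), sep=_sep(Path(path)), float_precision="round_trip"
    )
    features = list(dict.fromkeys(df["feature"].astype(str)))
    cell_types = list(dict.fromkeys(df["cell_type"].astype(str)))
    m, k = len(features), len(cell_types)
    shape = {name: np.full((m, k), np.nan) for name in
             ("effect", "se", "statistic", "pvalue")}
    joint_stat = np.full(m, np.nan)
    joint_p = np.full(m, np.nan)
    fidx = {f: i for i, f in enumerate(features)}
    cidx = {c: i for i, c in enumerate(cell_types)}
    for _, row in df.iterrows():
        j, h = fidx[str(row["feature"])], cidx[str(row["cell_type"])]
        for name in shape:
            shape[name][j, h] = row[name]
        joint_stat[j] = row["joint_statistic"]
        joint_p[j] = row["joint_pvalue"]
    return AssociationResult(
        effects=shape["effect"],
        standard_errors=shape["se"],
        statistics=shape["statistic"],
        pvalues=shape["pvalue"],
        joint_statistics=joint_stat,
        joint_pvalues=joint_p,
        mode=str(df["mode"].iloc[0]),
        feature_ids=features,
        cell_type_ids=cell_types,
    )


def load_covariates(cell_path=None, tissue_path=None) -> CovariateSet:
    cell = tissue = None
    cell_names = tissue_names = None
    if cell_path is not None:
        cell, _, cell_names = read_matrix(cell_path, "covariates")
    if tissue_path is not None:
        tissue, _, tissue_names = read_matrix(tissue_path, "covariates")
    return CovariateSet(cell, tissue, cell_names, tissue_names)
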