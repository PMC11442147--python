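"""Readers, writers and cohort-level preprocessing.

Three on-disk dialects are supported, all round-tripping the same
annotations:

* ``h5ad`` — AnnData HDF5; annotations live in ``obs`` columns.
* ``mtx`` — 10x-style triplet directory (``matrix.mtx`` genes x cells,
  ``features.tsv`` with id + symbol columns, ``barcodes.tsv``) plus a
  ``cells.csv`` sidecar holding the per-cell annotations.
* ``csv`` — dense ``expression.csv`` (cells as rows, genes as columns) with
  the same ``cells.csv`` sidecar next to it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import SCDataset
from .exceptions import (
    AlreadyNormalizedError,
    AnnotationKeyError,
    ConditionCardinalityError,
    EmptyResultError,
    PatientConsistencyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_dataset",
    "save_dataset",
    "normalize_counts",
    "filter_cell_types",
]

_FORMATS = ("h5ad", "mtx", "csv")


def _encode_condition(values: pd.Series, positive_label: str) -> np.ndarray:
    distinct = pd.unique(values.astype(str))
    if len(distinct) != 2:
        raise ConditionCardinalityError(
            f"condition column must hold exactly 2 values, found {len(distinct)}: "
            f"{sorted(map(str, distinct))}"
        )
    if str(positive_label) not in set(distinct):
        raise ConditionCardinalityError(
            f"positive_label {positive_label!r} not among condition values "
            f"{sorted(map(str, distinct))}"
        )
    return (values.astype(str) == str(positive_label)).to_numpy().astype(np.int8)


def _check_keys(df: pd.DataFrame, keys: dict[str, str]) -> None:
    for role, key in keys.items():
        if key not in df.columns:
            raise AnnotationKeyError(
                f"annotation column {key!r} (role: {role}) not found; "
                f"available: {list(df.columns)}"
            )


def _build(
    counts,
    gene_ids,
    cell_ids,
    obs: pd.DataFrame,
    patient_key: str,
    condition_key: str,
    celltype_key: str,
    positive_label: str,
    normalized: bool = False,
    layer: str = "raw",
) -> SCDataset:
    _check_keys(
        obs,
        {"patient": patient_key, "condition": condition_key, "cell_type": celltype_key},
    )
    condition = _encode_condition(obs[condition_key], positive_label)
    return SCDataset(
        counts=counts,
        gene_ids=np.asarray(gene_ids),
        cell_ids=np.asarray(cell_ids),
        patient=obs[patient_key].to_numpy(),
        condition=condition,
        cell_type=obs[celltype_key].to_numpy(),
        normalized=normalized,
        layer=layer,
    )


def load_dataset(
    path,
    format: str | None = None,
    patient_key: str = "patient",
    condition_key: str = "condition",
    celltype_key: str = "cell_type",
    positive_label: str = "1",
) -> SCDataset:
    """Load an annotated cohort from disk.

    ``positive_label`` names the condition value mapped to 1 (perturbed);
    the other value becomes 0. The format is inferred from the path when
    not given (directory -> mtx, ``.h5ad`` -> h5ad, else csv).
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "mtx"
        elif path.suffix == ".h5ad":
            format = "h5ad"
        else:
            format = "csv"
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "h5ad":
        return _load_h5ad(path, patient_key, condition_key, celltype_key, positive_label)
    if format == "mtx":
        return _load_mtx(path, patient_key, condition_key, celltype_key, positive_label)
    return _load_csv(path, patient_key, condition_key, celltype_key, positive_label)


def _load_h5ad(path, patient_key, condition_key, celltype_key, positive_label):
    import anndata as ad

    adata = ad.read_h5ad(path)
    return _build(
        adata.X if not sp.issparse(adata.X) else adata.X.tocsr(),
        adata.var_names.to_numpy(),
        adata.obs_names.to_numpy(),
        adata.obs,
        patient_key,
        condition_key,
        celltype_key,
        positive_label,
        normalized=bool(adata.uns.get("normalized", False)),
        layer=str(adata.uns.get("layer", "raw")),
    )


def _read_annotations(path: Path) -> pd.DataFrame:
    ann_path = path / "cells.csv" if path.is_dir() else path.parent / "cells.csv"
    if not ann_path.exists():
        raise AnnotationKeyError(
            f"annotation sidecar not found: {ann_path} (expected cells.csv keyed by cell id)"
        )
    return pd.read_csv(ann_path, index_col=0, dtype=str)


def _load_mtx(path, patient_key, condition_key, celltype_key, positive_label):
    path = Path(path)
    # on disk genes x cells (10x convention); transpose to cells x genes
    mat = scipy.io.mmread(path / "matrix.mtx").T.tocsr()
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None, dtype=str)
    gene_ids = features[0].to_numpy()
    cell_ids = barcodes[0].to_numpy()
    obs = _read_annotations(path).loc[cell_ids]
    return _build(
        mat, gene_ids, cell_ids, obs,
        patient_key, condition_key, celltype_key, positive_label,
    )


def _load_csv(path, patient_key, condition_key, celltype_key, positive_label):
    path = Path(path)
    expr = pd.read_csv(path, index_col=0)
    obs = _read_annotations(path).loc[expr.index.astype(str)]
    return _build(
        expr.to_numpy(dtype=np.float64),
        expr.columns.to_numpy(),
        expr.index.to_numpy(),
        obs,
        patient_key, condition_key, celltype_key, positive_label,
    )


def save_dataset(ds: SCDataset, path, format: str = "h5ad") -> Path:
    """Write a dataset in any supported dialect; returns the path written."""
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "h5ad":
        path.parent.mkdir(parents=True, exist_ok=True)
        ds.to_anndata().write_h5ad(path)
        return path
    path.mkdir(parents=True, exist_ok=True) if format == "mtx" else path.parent.mkdir(
        parents=True, exist_ok=True
    )
    ann = pd.DataFrame(
        {
            "patient": ds.patient,
            "condition": ds.condition.astype(int).astype(str),
            "cell_type": ds.cell_type,
        },
        index=pd.Index(ds.cell_ids, name="cell_id"),
    )
    if format == "mtx":
        mat = sp.coo_matrix(ds.counts).T  # genes x cells on disk
        scipy.io.mmwrite(str(path / "matrix.mtx"), mat)
        pd.DataFrame({0: ds.gene_ids, 1: ds.gene_ids}).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(ds.cell_ids).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        ann.to_csv(path / "cells.csv")
        return path
    # csv
    pd.DataFrame(ds.dense(), index=ds.cell_ids, columns=ds.gene_ids).to_csv(path)
    ann.to_csv(path.parent / "cells.csv")
    return path


def normalize_counts(ds: SCDataset, scale: float = 1e4) -> SCDataset:
    """Depth-normalize to ``scale`` counts per cell, then log1p.

    Cells with zero total counts are removed (their count is logged).
    Raises :class:`AlreadyNormalizedError` for already-normalized input;
    externally corrected matrices (``layer == "corrected"``) bypass via the
    caller simply not invoking this.
    """
    if ds.normalized:
        raise AlreadyNormalizedError("dataset is already normalized")
    X = ds.counts
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        totals = np.asarray(X, dtype=np.float64).sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("normalize_counts: dropped %d zero-count cell(s)", n_dropped)
        ds = ds.take_cells(np.flatnonzero(keep))
        totals = totals[keep]
    if sp.issparse(ds.counts):
        X = sp.csr_matrix(ds.counts, dtype=np.float64)
        X = sp.diags(scale / totals) @ X
        X.data = np.log1p(X.data)
    else:
        X = np.asarray(ds.counts, dtype=np.float64) * (scale / totals)[:, None]
        X = np.log1p(X)
    from dataclasses import replace

    return replace(ds, counts=X, normalized=True, layer="lognorm")


def filter_cell_types(
    ds: SCDataset, min_cells: int = 20, min_patients: int = 3
) -> SCDataset:
    """Retain cell types sufficiently represented in *both* conditions.

    A cell type is kept when, within each condition separately, at least
    ``min_patients`` patients each contribute at least ``min_cells`` cells
    of that type. Removed types are logged. Idempotent.
    """
    df = pd.DataFrame(
        {"ct": ds.cell_type, "p": ds.patient, "c": ds.condition}
    )
    counts = df.groupby(["ct", "c", "p"]).size()
    kept = []
    for ct in ds.cell_types:
        ok = True
        for cond in (0, 1):
            try:
                per_patient = counts.loc[ct, cond]
            except KeyError:
                ok = False
                break
            if int((per_patient >= min_cells).sum()) < min_patients:
                ok = False
                break
        if ok:
            kept.append(ct)
    removed = sorted(set(ds.cell_types) - set(kept))
    if removed:
        logger.info("filter_cell_types: removed %s", removed)
    if not kept:
        raise EmptyResultError(
            f"no cell type passes min_cells={min_cells}, min_patients={min_patients}; "
            "consider relaxing the thresholds"
        )
    from .data import subset

    return subset(ds, cell_types=kept)
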