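"""In-memory containers for annotated single-cell expression cohorts.

The pipeline currency is :class:`SCDataset`: a cells x genes expression
matrix together with three per-cell annotations (patient, binary condition,
cell type). The condition is always encoded internally as ``0`` (reference)
and ``1`` (perturbed) and is constant within a patient — patients, not
cells, are the experimental unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import (
    InsufficientCohortError,
    PatientConsistencyError,
    UnknownIdError,
)

__all__ = ["SCDataset", "SplitSpec", "subset", "split_by_patient"]


def _as_str_array(values: Iterable, name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    return arr.astype(str)


@dataclass
class SCDataset:
    """Cells x genes expression with patient / condition / cell-type labels.

    Parameters
    ----------
    counts
        Non-negative matrix, cells x genes. May be dense ``ndarray`` or any
        scipy sparse matrix; the contract is value equality only.
    gene_ids, cell_ids
        Unique string identifiers for columns / rows.
    patient, condition, cell_type
        Per-cell annotations. ``condition`` is {0, 1} with 1 = perturbed.
    normalized
        Whether counts have been depth-normalized and log1p-transformed.
    layer
        Provenance tag: ``"raw"``, ``"lognorm"`` or ``"corrected"`` (an
        externally batch-corrected matrix that should bypass normalization).
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    patient: np.ndarray
    condition: np.ndarray
    cell_type: np.ndarray
    normalized: bool = False
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        self.patient = _as_str_array(self.patient, "patient")
        self.cell_type = _as_str_array(self.cell_type, "cell_type")
        self.condition = np.asarray(self.condition, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != n_genes {n_genes}"
            )
        for name, arr in (
            ("cell_ids", self.cell_ids),
            ("patient", self.patient),
            ("condition", self.condition),
            ("cell_type", self.cell_type),
        ):
            if len(arr) != n_cells:
                raise ValueError(f"{name} length {len(arr)} != n_cells {n_cells}")
        if len(np.unique(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids contain duplicates")
        if len(np.unique(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids contain duplicates")
        bad = set(np.unique(self.condition)) - {0, 1}
        if bad:
            raise ValueError(f"condition values outside {{0,1}}: {sorted(bad)}")
        # one condition per patient
        df = pd.DataFrame({"p": self.patient, "c": self.condition})
        mixed = df.groupby("p", sort=False)["c"].nunique()
        offenders = mixed.index[mixed > 1].tolist()
        if offenders:
            raise PatientConsistencyError(
                f"patient(s) with mixed conditions: {offenders}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def patients(self) -> np.ndarray:
        """Unique patient ids, sorted."""
        return np.unique(self.patient)

    @property
    def cell_types(self) -> np.ndarray:
        return np.unique(self.cell_type)

    def patient_condition(self) -> dict[str, int]:
        """Map patient id -> condition (constant within patient)."""
        out: dict[str, int] = {}
        for p, c in zip(self.patient, self.condition):
            out.setdefault(p, int(c))
        return out

    def dense(self) -> np.ndarray:
        """Expression as a dense float64 array (cells x genes)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=np.float64)
        return np.asarray(self.counts, dtype=np.float64)

    def take_cells(self, idx: np.ndarray) -> "SCDataset":
        """Row-subset by positional cell indices (internal plumbing)."""
        idx = np.asarray(idx)
        return replace(
            self,
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            patient=self.patient[idx],
            condition=self.condition[idx],
            cell_type=self.cell_type[idx],
        )

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (obs: patient/condition/cell_type)."""
        import anndata as ad

        obs = pd.DataFrame(
            {
                "patient": self.patient,
                "condition": self.condition.astype(int),
                "cell_type": self.cell_type,
            },
            index=pd.Index(self.cell_ids, name="cell_id"),
        )
        var = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        adata = ad.AnnData(X=self.counts, obs=obs, var=var)
        adata.uns["normalized"] = bool(self.normalized)
        adata.uns["layer"] = self.layer
        return adata


@dataclass(frozen=True)
class SplitSpec:
    """A patient-wise train/test partition."""

    train_patients: frozenset
    test_patients: frozenset
    seed: int

    def __post_init__(self) -> None:
        if self.train_patients & self.test_patients:
            raise ValueError("train and test patient sets overlap")


def subset(
    ds: SCDataset,
    patients: Iterable[str] | None = None,
    cell_types: Iterable[str] | None = None,
    genes: Sequence[str] | None = None,
) -> SCDataset:
    """Restrict a dataset to given patients, cell types and/or genes.

    Gene order in the result is exactly the order given in ``genes``.
    Unknown ids raise :class:`UnknownIdError` naming the offender.
    """
    mask = np.ones(ds.n_cells, dtype=bool)
    if patients is not None:
        patients = set(map(str, patients))
        missing = patients - set(ds.patients)
        if missing:
            raise UnknownIdError(f"unknown patient id(s): {sorted(missing)}")
        mask &= np.isin(ds.patient, list(patients))
    if cell_types is not None:
        cell_types = set(map(str, cell_types))
        missing = cell_types - set(ds.cell_types)
        if missing:
            raise UnknownIdError(f"unknown cell type(s): {sorted(missing)}")
        mask &= np.isin(ds.cell_type, list(cell_types))
    out = ds.take_cells(np.flatnonzero(mask))
    if genes is not None:
        genes = [str(g) for g in genes]
        pos = {g: i for i, g in enumerate(ds.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise UnknownIdError(f"unknown gene id(s): {missing}")
        cols = np.array([pos[g] for g in genes], dtype=int)
        out = replace(
            out,
            counts=out.counts[:, cols],
            gene_ids=np.array(genes, dtype=str),
        )
    return out


def split_by_patient(
    ds: SCDataset, test_fraction: float = 0.2, seed: int = 0
) -> SplitSpec:
    """Partition patients into train/test, stratified by condition.

    The test side receives ``round(test_fraction * n)`` patients per
    condition but never fewer than 1 and never all of them, so both sides
    always hold at least one patient of each condition. Deterministic for a
    given seed.
    """
    pc = ds.patient_condition()
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    test: set[str] = set()
    for cond in (0, 1):
        pats = sorted(p for p, c in pc.items() if c == cond)
        if len(pats) < 2:
            raise InsufficientCohortError(
                f"condition {cond} has {len(pats)} patient(s); >=2 required"
            )
        n_test = int(round(test_fraction * len(pats)))
        n_test = min(max(n_test, 1), len(pats) - 1)
        order = rng.permutation(len(pats))
        test.update(pats[i] for i in order[:n_test])
        train.update(pats[i] for i in order[n_test:])
    return SplitSpec(frozenset(train), frozenset(test), seed)
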