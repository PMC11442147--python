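"""Rank cell types by how well they separate the two patient conditions.

For each cell type, a random forest is repeatedly trained to predict the
perturbation label of single cells and scored by AUROC on *held-out
patients*. Splitting by patient — never by cell — is the crucial design
point: cells of one donor share donor-specific expression patterns, so a
cell-wise split lets the classifier recognise donors rather than the
perturbation and inflates the score of unresponsive cell types. Equal
numbers of cells are drawn from every patient so that large donors cannot
dominate, and the minority condition is up-weighted.

The mean held-out AUROC across repeats is the cell type's responsiveness
score; types are ranked by it.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .data import SCDataset, subset
from .exceptions import ConfigError, ScoringError, UnknownIdError

logger = logging.getLogger(__name__)

__all__ = [
    "ResponsivenessConfig",
    "CellTypeScore",
    "ResponsivenessTable",
    "subsample_equal_cells",
    "score_cell_type",
    "rank_cell_types",
]


@dataclass(frozen=True)
class ResponsivenessConfig:
    """Knobs of the cell-type scoring procedure.

    ``cells_per_patient`` is capped at the minimum available per patient in
    a type; ``internal_validation_fraction`` is the patient-stratified share
    of patients held out inside each repeat. ``split_by`` is ``"patient"``
    (default, leakage-safe) or ``"cell"`` (provided to demonstrate the
    donor-leakage inflation; never use for real scoring). ``max_genes``
    optionally restricts the forest to the most variable genes for speed.
    """

    n_repeats: int = 20
    cells_per_patient: int = 20
    internal_validation_fraction: float = 0.25
    rf_trees: int = 100
    rf_max_depth: int | None = None
    seed: int = 0
    split_by: str = "patient"
    max_genes: int | None = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if not (0.0 < self.internal_validation_fraction < 1.0):
            raise ConfigError("internal_validation_fraction must be in (0,1)")
        if self.split_by not in ("patient", "cell"):
            raise ConfigError("split_by must be 'patient' or 'cell'")


@dataclass
class CellTypeScore:
    cell_type: str
    mean_auroc: float
    auroc_per_repeat: list[float]
    n_cells_used: int
    n_patients_used: int
    rank: int | None = None


@dataclass
class ResponsivenessTable:
    """Per-type responsiveness scores, ranked (rank 1 = most responsive)."""

    entries: list[CellTypeScore]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_type": [e.cell_type for e in self.entries],
                "mean_auroc": [e.mean_auroc for e in self.entries],
                "n_cells_used": [e.n_cells_used for e in self.entries],
                "n_patients_used": [e.n_patients_used for e in self.entries],
                "rank": [e.rank for e in self.entries],
            }
        ).set_index("cell_type")

    def top(self, n: int = 1) -> list[str]:
        ordered = sorted(self.entries, key=lambda e: e.rank)
        return [e.cell_type for e in ordered[:n]]

    def __getitem__(self, cell_type: str) -> CellTypeScore:
        for e in self.entries:
            if e.cell_type == cell_type:
                return e
        raise UnknownIdError(f"cell type {cell_type!r} not in table")


def subsample_equal_cells(
    ds: SCDataset, cell_type: str, k: int, seed: int
) -> np.ndarray:
    """Indices (into ``ds``) of min(k, n_p) cells per patient of one type.

    Sampling is without replacement and deterministic under ``seed``;
    patients are visited in sorted order.
    """
    if cell_type not in ds.cell_types:
        raise UnknownIdError(f"cell type {cell_type!r} not present")
    rng = np.random.default_rng(seed)
    mask = ds.cell_type == cell_type
    chosen: list[np.ndarray] = []
    for pat in np.unique(ds.patient[mask]):
        idx = np.flatnonzero(mask & (ds.patient == pat))
        take = min(k, len(idx))
        chosen.append(rng.choice(idx, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


def _class_weights(y: np.ndarray) -> dict[int, float]:
    """weight(c) = n_total / (2 * n_c): up-weights the minority condition."""
    n = len(y)
    return {c: n / (2.0 * np.sum(y == c)) for c in (0, 1)}


def _split_patients_stratified(
    patients: np.ndarray,
    labels: dict[str, int],
    val_fraction: float,
    rng: np.random.Generator,
) -> tuple[set, set]:
    train: set = set()
    val: set = set()
    for cond in (0, 1):
        pats = sorted(p for p in patients if labels[p] == cond)
        n_val = int(round(val_fraction * len(pats)))
        n_val = min(max(n_val, 1), len(pats) - 1)
        order = rng.permutation(len(pats))
        val.update(pats[i] for i in order[:n_val])
        train.update(pats[i] for i in order[n_val:])
    return train, val


def score_cell_type(
    ds: SCDataset, cell_type: str, cfg: ResponsivenessConfig
) -> CellTypeScore:
    """Patient-held-out random-forest AUROC for one cell type.

    Each repeat: draw an equal number of cells per patient, hold out a
    condition-stratified set of patients, fit a class-weighted random
    forest on the remaining patients' cells and score AUROC on the held-out
    cells. Repeats whose validation side ends up single-condition are
    redrawn (up to 10 attempts) and finally skipped with a warning.
    """
    sub = subset(ds, cell_types={cell_type})
    labels = sub.patient_condition()
    for cond in (0, 1):
        if sum(1 for c in labels.values() if c == cond) < 2:
            raise ScoringError(
                f"cell type {cell_type!r}: need >=2 patients per condition"
            )
    X_full = sub.dense()
    gene_sel = None
    if cfg.max_genes is not None and cfg.max_genes < sub.n_genes:
        var = X_full.var(axis=0)
        gene_sel = np.argsort(var)[::-1][: cfg.max_genes]
        X_full = X_full[:, gene_sel]

    # stable per-type substream (str hash() is randomized per process)
    ss = np.random.SeedSequence([cfg.seed, zlib.crc32(cell_type.encode()) % (2**31)])
    repeat_seeds = ss.generate_state(cfg.n_repeats * 2).reshape(-1, 2)
    aurocs: list[float] = []
    n_cells_used = 0
    for r in range(cfg.n_repeats):
        sub_seed, split_seed = int(repeat_seeds[r, 0]), int(repeat_seeds[r, 1])
        idx = subsample_equal_cells(sub, cell_type, cfg.cells_per_patient, sub_seed)
        X = X_full[idx]
        y = sub.condition[idx]
        pats = sub.patient[idx]
        rng = np.random.default_rng(split_seed)
        auroc = None
        for _attempt in range(10):
            if cfg.split_by == "patient":
                train_p, val_p = _split_patients_stratified(
                    np.unique(pats), labels, cfg.internal_validation_fraction, rng
                )
                tr = np.isin(pats, list(train_p))
                va = np.isin(pats, list(val_p))
                assert not (set(pats[tr]) & set(pats[va])), "patient leak across split"
            else:  # cell-wise split: retained only to demonstrate leakage
                perm = rng.permutation(len(y))
                n_val = max(1, int(round(cfg.internal_validation_fraction * len(y))))
                va = np.zeros(len(y), dtype=bool)
                va[perm[:n_val]] = True
                tr = ~va
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            clf = RandomForestClassifier(
                n_estimators=cfg.rf_trees,
                max_depth=cfg.rf_max_depth,
                class_weight=_class_weights(y[tr]),
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            clf.fit(X[tr], y[tr])
            prob = clf.predict_proba(X[va])[:, list(clf.classes_).index(1)]
            auroc = float(roc_auc_score(y[va], prob))
            break
        if auroc is None:
            warnings.warn(
                f"score_cell_type({cell_type}): repeat {r} skipped "
                "(single-condition validation fold after 10 attempts)"
            )
            continue
        aurocs.append(auroc)
        n_cells_used = max(n_cells_used, len(idx))
    if not aurocs:
        raise ScoringError(f"all repeats failed for cell type {cell_type!r}")
    return CellTypeScore(
        cell_type=cell_type,
        mean_auroc=float(np.mean(aurocs)),
        auroc_per_repeat=aurocs,
        n_cells_used=n_cells_used,
        n_patients_used=len(labels),
    )


def rank_cell_types(
    ds: SCDataset, cfg: ResponsivenessConfig | None = None
) -> ResponsivenessTable:
    """Score every cell type present and rank by mean AUROC (descending).

    Ties are broken toward the type with more cells, then lexicographic
    name. Types whose scoring fails are excluded with a warning.
    """
    cfg = cfg or ResponsivenessConfig()
    entries: list[CellTypeScore] = []
    for ct in ds.cell_types:
        try:
            entries.append(score_cell_type(ds, ct, cfg))
        except ScoringError as exc:
            warnings.warn(f"rank_cell_types: skipping {ct!r}: {exc}")
    if not entries:
        raise ScoringError("no cell type could be scored")
    n_cells = {ct: int(np.sum(ds.cell_type == ct)) for ct in ds.cell_types}
    entries.sort(key=lambda e: (-e.mean_auroc, -n_cells[e.cell_type], e.cell_type))
    for i, e in enumerate(entries):
        e.rank = i + 1
    return ResponsivenessTable(entries)
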