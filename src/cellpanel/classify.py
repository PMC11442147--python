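"""Ensemble cell-state classifiers and patient-level aggregation.

Five classifiers — logistic regression, linear SVM, random forest,
distance-weighted kNN and a graph attention network — are trained on the
selected cell type restricted to the selected gene panel. Their per-cell
probabilities are combined by the elementwise median (the consensus).

A patient's score is the AUC-style rank statistic of its cells' consensus
probabilities against the 0.5 decision reference:

    AUC_p = (#{prob > 0.5} + 0.5 * #{prob = 0.5}) / n_cells

so a patient whose cells are confidently called perturbed scores near 1
and a reference patient near 0. Significance against 0.5 comes from a
one-sided bootstrap over that patient's cells. Cells are weighted so that
every patient contributes equally within its condition and both conditions
contribute equally overall.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from scipy.spatial.distance import cdist
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from .data import SCDataset, subset
from .exceptions import ConfigError, MissingGenesError, SingleClassError
from .gat import GATClassifier, GATConfig
from .genes import GenePanel, _standardize

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "EnsembleModel",
    "CellPredictions",
    "PatientReport",
    "compute_cell_weights",
    "build_cell_graph",
    "train_ensemble",
    "predict_cells",
    "patient_auc",
    "bootstrap_pvalue",
    "classify_patients",
]

MEMBERS = ("LR", "SVM", "RF", "kNN", "GAT")


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the five ensemble members (all configurable)."""

    rf_trees: int = 100
    knn_neighbors: int = 15
    graph_k: int = 15
    svm_c: float = 1.0
    lr_c: float = 1.0
    gat: GATConfig = field(default_factory=GATConfig)
    members: tuple[str, ...] = MEMBERS
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.members) - set(MEMBERS)
        if unknown:
            raise ConfigError(f"unknown ensemble member(s): {sorted(unknown)}")
        if not self.members:
            raise ConfigError("ensemble needs at least one member")


def compute_cell_weights(patient: np.ndarray, condition: np.ndarray) -> np.ndarray:
    """Per-cell weights balancing patients within condition and conditions.

    ``w_i = N / (2 * P_c(i) * n_p(i))`` with N total cells, ``P_c`` the
    number of patients in cell i's condition and ``n_p`` the cell count of
    its patient. Consequently each patient contributes total weight
    ``N / (2 P_c)`` and each condition total ``N / 2``.
    """
    patient = np.asarray(patient)
    condition = np.asarray(condition)
    if len(np.unique(condition)) < 2:
        raise SingleClassError("both conditions must be present")
    n_total = len(patient)
    pat_cond = {}
    pat_cells = {}
    for p, c in zip(patient, condition):
        pat_cond[p] = int(c)
        pat_cells[p] = pat_cells.get(p, 0) + 1
    patients_per_class = {
        c: sum(1 for v in pat_cond.values() if v == c) for c in (0, 1)
    }
    w = np.empty(n_total, dtype=float)
    for i, (p, c) in enumerate(zip(patient, condition)):
        w[i] = n_total / (2.0 * patients_per_class[int(c)] * pat_cells[p])
    return w


def build_cell_graph(X: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Symmetrized k-nearest-neighbour graph on standardized panel features.

    Euclidean distances, brute force for determinism (ties resolve by
    index order); an edge exists when either endpoint selects the other.
    ``k`` is clipped to n_cells - 1 with a warning when too large.
    """
    n = X.shape[0]
    if k >= n:
        warnings.warn(f"build_cell_graph: k={k} >= n_cells={n}; clipping")
        k = n - 1
    if k < 1:
        raise ConfigError("need at least 2 cells to build a graph")
    X = np.asarray(X, dtype=np.float64)
    rows, cols = [], []
    chunk = max(1, int(2e7 // max(n, 1)))  # bound the distance-block memory
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(X[start:stop], X)
        d[np.arange(stop - start), np.arange(start, stop)] = np.inf  # no self
        # stable sort: equidistant neighbours resolve to the lower index
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        rows.append(np.repeat(np.arange(start, stop), k))
        cols.append(order.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)  # symmetrize
    return adj


@dataclass
class EnsembleModel:
    """Fitted ensemble members plus everything needed to predict later."""

    members: dict
    panel: GenePanel
    cell_type: str
    feature_mean: np.ndarray
    feature_std: np.ndarray
    graph_k: int
    config: EnsembleConfig


@dataclass
class CellPredictions:
    """Per-cell probabilities per member plus the median consensus."""

    cell_ids: np.ndarray
    patient: np.ndarray
    member_probs: pd.DataFrame  # columns = member names
    consensus: np.ndarray
    condition: np.ndarray | None = None  # true label when known

    def to_frame(self) -> pd.DataFrame:
        df = self.member_probs.copy()
        df.insert(0, "patient", self.patient)
        df["consensus"] = self.consensus
        if self.condition is not None:
            df["condition"] = self.condition
        df.index = pd.Index(self.cell_ids, name="cell_id")
        return df


def _holdout_mask(
    patient: np.ndarray, condition: np.ndarray, fraction: float, rng
) -> np.ndarray:
    """Boolean mask of cells in a patient-stratified held-out set."""
    labels = {}
    for p, c in zip(patient, condition):
        labels.setdefault(p, int(c))
    held: set = set()
    for cond in (0, 1):
        pats = sorted(p for p, c in labels.items() if c == cond)
        if len(pats) < 2:
            continue
        n_val = min(max(1, int(round(fraction * len(pats)))), len(pats) - 1)
        order = rng.permutation(len(pats))
        held.update(pats[i] for i in order[:n_val])
    return np.isin(patient, list(held))


def train_ensemble(
    train: SCDataset, weights: np.ndarray | None = None, seed: int = 0,
    cfg: EnsembleConfig | None = None,
) -> EnsembleModel:
    """Fit all ensemble members on one cell type restricted to the panel.

    ``train`` must already be restricted to the selected cell type and
    panel genes (in panel order). Features are standardized here and the
    statistics stored for prediction time. The GAT trains on a cell graph
    with an internal patient-held-out split for early stopping.
    """
    cfg = cfg or EnsembleConfig(seed=seed)
    if len(np.unique(train.condition)) < 2:
        raise SingleClassError("training data must contain both conditions")
    if weights is None:
        weights = compute_cell_weights(train.patient, train.condition)
    X, mean, std = _standardize(train.dense())
    y = train.condition.astype(int)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(MEMBERS))
    members: dict = {}
    for name in cfg.members:
        s = int(seeds[MEMBERS.index(name)] % (2**31))
        if name == "LR":
            clf = LogisticRegression(C=cfg.lr_c, max_iter=2000, random_state=s)
            clf.fit(X, y, sample_weight=weights)
        elif name == "SVM":
            # linear SVM (liblinear) with Platt-calibrated probabilities
            clf = CalibratedClassifierCV(
                LinearSVC(C=cfg.svm_c, dual=False, random_state=s),
                ensemble=False,
            )
            clf.fit(X, y, sample_weight=weights)
        elif name == "RF":
            clf = RandomForestClassifier(
                n_estimators=cfg.rf_trees, random_state=s, n_jobs=1
            )
            clf.fit(X, y, sample_weight=weights)
        elif name == "kNN":
            # kNN has no sample-weight notion; distance weighting only
            clf = KNeighborsClassifier(
                n_neighbors=min(cfg.knn_neighbors, len(y) - 1), weights="distance"
            )
            clf.fit(X, y)
        elif name == "GAT":
            adj = build_cell_graph(X, k=cfg.graph_k)
            rng = np.random.default_rng(s)
            val = _holdout_mask(train.patient, train.condition, 0.25, rng)
            from dataclasses import replace as _rep

            clf = GATClassifier(_rep(cfg.gat, seed=s))
            clf.fit(
                X, y, adj, sample_weight=weights,
                train_mask=~val, val_mask=val,
            )
        members[name] = clf
    if len(members) < len(MEMBERS):
        missing = sorted(set(MEMBERS) - set(members))
        warnings.warn(
            f"ensemble trained with {len(members)} member(s); missing: {missing}. "
            "Consensus will be the median of the available members."
        )
    return EnsembleModel(
        members=members,
        panel=GenePanel(
            genes=[str(g) for g in train.gene_ids],
            n_selected=train.n_genes,
            source_cell_type=str(train.cell_type[0]) if train.n_cells else "",
        ),
        cell_type=str(train.cell_type[0]) if train.n_cells else "",
        feature_mean=mean,
        feature_std=std,
        graph_k=cfg.graph_k,
        config=cfg,
    )


def predict_cells(model: EnsembleModel, test: SCDataset) -> CellPredictions:
    """Per-cell probabilities from every member plus the median consensus.

    Test features are reordered to the panel and transformed with the
    *training* standardization statistics. Missing panel genes are a hard
    error — silently imputing zeros would corrupt the probabilities.
    """
    missing = [g for g in model.panel.genes if g not in set(test.gene_ids)]
    if missing:
        raise MissingGenesError(f"panel gene(s) absent from test data: {missing}")
    test = subset(test, genes=model.panel.genes)
    X = (test.dense() - model.feature_mean) / model.feature_std
    probs = {}
    for name, clf in model.members.items():
        if name == "GAT":
            adj = build_cell_graph(X, k=min(model.graph_k, max(1, X.shape[0] - 1)))
            p = clf.predict_proba(X, adj)[:, 1]
        else:
            p = clf.predict_proba(X)[:, list(clf.classes_).index(1)]
        probs[name] = p
    member_probs = pd.DataFrame(probs)
    consensus = member_probs.to_numpy().copy()
    consensus = np.median(consensus, axis=1)
    return CellPredictions(
        cell_ids=test.cell_ids,
        patient=test.patient,
        member_probs=member_probs,
        consensus=consensus,
        condition=test.condition,
    )


def patient_auc(probs: np.ndarray) -> float:
    """Rank of a patient's cell probabilities against the 0.5 reference.

    ``(#{p > 0.5} + 0.5 * #{p = 0.5}) / n`` — 1.0 when every cell is
    confidently perturbed, 0.0 when every cell is confidently reference.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("patient_auc: need at least one cell")
    return float(
        (np.sum(probs > 0.5) + 0.5 * np.sum(probs == 0.5)) / probs.size
    )


def bootstrap_pvalue(probs: np.ndarray, B: int = 1000, seed: int = 0) -> float:
    """One-sided bootstrap significance of a patient's AUC versus 0.5.

    The patient's cells are resampled with replacement B times; p is the
    add-one-corrected fraction of replicate AUCs falling on the opposite
    side of 0.5 from the observed AUC (or exactly on it). An observed AUC
    of exactly 0.5 returns p = 1.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size < 2:
        raise ValueError("bootstrap_pvalue: need >= 2 cells")
    if B < 100:
        warnings.warn(f"bootstrap_pvalue: B={B} is small; p will be unstable")
    obs = patient_auc(probs)
    if obs == 0.5:
        return 1.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, probs.size, size=(B, probs.size))
    res = probs[idx]
    reps = (np.sum(res > 0.5, axis=1) + 0.5 * np.sum(res == 0.5, axis=1)) / probs.size
    if obs > 0.5:
        extreme = np.sum(reps <= 0.5)
    else:
        extreme = np.sum(reps >= 0.5)
    return float((1 + extreme) / (B + 1))


@dataclass
class PatientReport:
    """Per-patient scores and, when truth is known, cohort-level metrics."""

    per_patient: pd.DataFrame  # auc, p_value, predicted_label, n_cells, ...
    metrics: dict | None = None

    def summary(self) -> str:
        lines = [self.per_patient.to_string()]
        if self.metrics:
            lines.append("")
            lines.append(
                "  ".join(f"{k}={v:.3f}" for k, v in self.metrics.items())
            )
        return "\n".join(lines)


def classify_patients(
    preds: CellPredictions,
    truth: dict | None = None,
    B: int = 1000,
    seed: int = 0,
) -> PatientReport:
    """Aggregate cell consensus probabilities into per-patient calls.

    A patient is called perturbed when its AUC exceeds 0.5; an AUC of
    exactly 0.5 is flagged undetermined and counted as reference. With
    known truth, cohort accuracy / precision / sensitivity / specificity /
    F1 are computed on the hard labels (positive class = perturbed).
    """
    if truth is None and preds.condition is not None:
        truth = {
            p: int(c)
            for p, c in zip(preds.patient, preds.condition)
        }
    rows = []
    ss = np.random.SeedSequence(seed)
    pats = sorted(set(preds.patient))
    pat_seeds = {p: int(s % (2**31)) for p, s in zip(pats, ss.generate_state(len(pats)))}
    for pat in pats:
        pr = preds.consensus[preds.patient == pat]
        auc = patient_auc(pr)
        p_val = bootstrap_pvalue(pr, B=B, seed=pat_seeds[pat]) if pr.size >= 2 else 1.0
        label = 1 if auc > 0.5 else 0
        rows.append(
            {
                "patient": pat,
                "auc": auc,
                "p_value": p_val,
                "predicted_label": label,
                "undetermined": auc == 0.5,
                "n_cells": int(pr.size),
                "true_label": truth.get(pat) if truth else None,
            }
        )
    df = pd.DataFrame(rows).set_index("patient")
    metrics = None
    if truth is not None and df["true_label"].notna().all():
        y_true = df["true_label"].astype(int).to_numpy()
        y_pred = df["predicted_label"].to_numpy()
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        # empty denominators read as 1.0: no error of that kind was possible
        sens = tp / (tp + fn) if tp + fn else 1.0
        spec = tn / (tn + fp) if tn + fp else 1.0
        prec = tp / (tp + fp) if tp + fp else 1.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        metrics = {
            "accuracy": (tp + tn) / len(y_true),
            "precision": prec,
            "sensitivity": sens,
            "specificity": spec,
            "f1": f1,
        }
    return PatientReport(per_patient=df, metrics=metrics)
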