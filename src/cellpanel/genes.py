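"""Sparse gene-panel selection by SVM recursive feature elimination.

A linear SVM is fitted on all genes of the chosen cell type; at each
iteration the genes with the smallest squared weight are removed (a fixed
percentage, 3% by default, of the genes still in play — at least one).
Running the elimination inside a patient-grouped k-fold cross-validation
yields a curve of held-out balanced accuracy versus the number of genes
retained; the parsimonious panel size is the point of the curve at maximal
perpendicular distance from the chord joining its endpoints (the classic
elbow / perpendicular-line rule). The final panel is the top genes of a
full-data elimination ranking.

A stable mode repeats the whole selection on patient-level downsamples of
the cohort and keeps genes chosen in more than a threshold fraction of
subsets, trading a little sparsity for robustness to cohort composition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import LinearSVC

from .data import SCDataset, subset
from .exceptions import (
    ConfigError,
    DegenerateCurveError,
    InsufficientCohortError,
    SingleClassError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSelectionConfig",
    "RFECurve",
    "GenePanel",
    "elimination_schedule",
    "svm_rfe_rank",
    "cv_accuracy_curve",
    "find_elbow",
    "select_gene_panel",
    "stable_gene_panel",
]


@dataclass(frozen=True)
class GeneSelectionConfig:
    """Parameters of panel selection.

    ``elimination_fraction`` is the share of currently surviving genes
    removed per elimination step; ``k_folds`` the number of patient-grouped
    CV folds used for the accuracy curve; ``svm_c`` the SVM regularization
    strength. ``low_confidence_accuracy`` flags panels whose best curve
    accuracy never reaches the threshold.
    """

    k_folds: int = 5
    elimination_fraction: float = 0.03
    svm_c: float = 1.0
    max_iter: int = 5000
    low_confidence_accuracy: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.elimination_fraction < 1.0):
            raise ConfigError("elimination_fraction must be in (0,1)")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")


@dataclass
class RFECurve:
    """Held-out accuracy per panel size, averaged over CV folds."""

    gene_counts: np.ndarray  # strictly decreasing, starts at n_genes
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    k_folds: int
    elimination_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_genes": self.gene_counts,
                "mean_accuracy": self.mean_accuracy,
                "sd_accuracy": self.sd_accuracy,
            }
        )


@dataclass
class GenePanel:
    """An ordered panel (most informative first) for one cell type."""

    genes: list[str]
    n_selected: int
    source_cell_type: str
    selection_frequency: dict[str, float] | None = None
    low_confidence: bool = False
    curve: RFECurve | None = None
    subset_panels: list[list[str]] | None = None  # stable mode bookkeeping

    def __post_init__(self) -> None:
        if self.n_selected != len(self.genes):
            raise ValueError("n_selected != len(genes)")


def elimination_schedule(n_genes: int, fraction: float = 0.03) -> list[int]:
    """Panel sizes visited by percentage elimination, from n_genes down to 1.

    Each step removes ``max(1, floor(fraction * current))`` genes.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    if not (0.0 < fraction < 1.0):
        raise ConfigError("fraction must be in (0,1)")
    sched = [n_genes]
    cur = n_genes
    while cur > 1:
        cur -= max(1, int(fraction * cur))
        sched.append(cur)
    return sched


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return (X - mean) / std, mean, std


def _fit_linear_svm(X, y, sample_weight, C, max_iter, seed=0) -> LinearSVC:
    clf = LinearSVC(
        C=C,
        dual=False,
        tol=1e-2,
        max_iter=max_iter,
        class_weight="balanced",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter
        clf.fit(X, y, sample_weight=sample_weight)
    return clf


def _rfe_path(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None,
    fraction: float,
    C: float,
    max_iter: int,
    eval_X: np.ndarray | None = None,
    eval_y: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int], list[float] | None]:
    """Shared elimination engine.

    Returns ``(ranking, schedule, accuracies)`` where ``ranking`` assigns 1
    to the gene surviving longest, and ``accuracies`` (when eval data is
    given) is the held-out balanced accuracy of the SVM fitted at each
    schedule size — the same estimator that drives the elimination.
    """
    n_genes = X.shape[1]
    surviving = np.arange(n_genes)
    rank = np.empty(n_genes, dtype=int)
    next_worst = n_genes  # ranks are assigned from the bottom up
    sched = []
    accs: list[float] | None = [] if eval_X is not None else None
    while True:
        sched.append(len(surviving))
        clf = _fit_linear_svm(X[:, surviving], y, sample_weight, C, max_iter)
        if accs is not None:
            pred = clf.predict(eval_X[:, surviving])
            accs.append(float(balanced_accuracy_score(eval_y, pred)))
        if len(surviving) == 1:
            rank[surviving[0]] = 1
            break
        w2 = np.ravel(clf.coef_) ** 2
        n_drop = max(1, int(len(surviving) * fraction))
        order = np.argsort(w2, kind="stable")  # smallest weight first
        dropped = order[:n_drop]
        # genes dropped together: smaller weight -> worse rank
        for j in dropped[::-1]:
            rank[surviving[j]] = next_worst
            next_worst -= 1
        keep = np.ones(len(surviving), dtype=bool)
        keep[dropped] = False
        surviving = surviving[keep]
    return rank, sched, accs


def svm_rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray | None = None,
    fraction: float = 0.03,
    C: float = 1.0,
    max_iter: int = 5000,
) -> np.ndarray:
    """Total elimination order over genes; rank 1 survives longest.

    ``X`` must be standardized (zero mean, unit variance per gene).
    """
    if len(np.unique(y)) < 2:
        raise SingleClassError("both classes must be present")
    rank, _, _ = _rfe_path(X, y, sample_weights, fraction, C, max_iter)
    return rank


def _grouped_stratified_folds(
    labels: dict[str, int], k: int, rng: np.random.Generator
) -> list[set]:
    """Partition patients into k folds, stratified by condition."""
    folds: list[set] = [set() for _ in range(k)]
    for cond in (0, 1):
        pats = sorted(p for p, c in labels.items() if c == cond)
        order = rng.permutation(len(pats))
        for i, j in enumerate(order):
            folds[i % k].add(pats[j])
    return folds


def cv_accuracy_curve(
    ds: SCDataset, k: int = 5, cfg: GeneSelectionConfig | None = None
) -> RFECurve:
    """Accuracy-vs-panel-size curve from patient-grouped k-fold CV.

    ``ds`` must already be restricted to one cell type. Folds partition
    patients (stratified by condition); within each fold genes are ranked
    on the training cells and the SVM at each elimination step is scored on
    the held-out fold's cells (balanced accuracy). Features are
    standardized with training-fold statistics. If fewer than ``k``
    patients per condition are available, k is lowered (minimum 2).
    """
    cfg = cfg or GeneSelectionConfig(k_folds=k)
    labels = ds.patient_condition()
    n_per_cond = min(
        sum(1 for c in labels.values() if c == 0),
        sum(1 for c in labels.values() if c == 1),
    )
    if n_per_cond < 2:
        raise InsufficientCohortError("need >=2 patients per condition for CV")
    if k > n_per_cond:
        logger.info("cv_accuracy_curve: lowering k from %d to %d", k, n_per_cond)
        k = n_per_cond
    rng = np.random.default_rng(cfg.seed)
    folds = _grouped_stratified_folds(labels, k, rng)
    X_all = ds.dense()
    sched_ref = elimination_schedule(ds.n_genes, cfg.elimination_fraction)
    per_fold = np.empty((k, len(sched_ref)))
    for fi, val_p in enumerate(folds):
        va = np.isin(ds.patient, list(val_p))
        tr = ~va
        assert not (set(ds.patient[tr]) & set(ds.patient[va]))
        Xtr, mean, std = _standardize(X_all[tr])
        Xva = (X_all[va] - mean) / std
        _, sched, accs = _rfe_path(
            Xtr,
            ds.condition[tr],
            None,
            cfg.elimination_fraction,
            cfg.svm_c,
            cfg.max_iter,
            eval_X=Xva,
            eval_y=ds.condition[va],
        )
        assert sched == sched_ref
        per_fold[fi] = accs
    return RFECurve(
        gene_counts=np.array(sched_ref),
        mean_accuracy=per_fold.mean(axis=0),
        sd_accuracy=per_fold.std(axis=0, ddof=1) if k > 1 else np.zeros(len(sched_ref)),
        k_folds=k,
        elimination_fraction=cfg.elimination_fraction,
    )


def find_elbow(curve: RFECurve) -> int:
    """Parsimonious gene count by the perpendicular-line rule.

    With curve points ordered by increasing gene count, the chord joining
    the first and last points is drawn and the point at maximal
    perpendicular distance is the elbow; ties resolve to the smaller count
    (sparser panel). A perfectly collinear curve returns the smallest count
    with a warning.
    """
    order = np.argsort(curve.gene_counts)
    x = np.asarray(curve.gene_counts, dtype=float)[order]
    y = np.asarray(curve.mean_accuracy, dtype=float)[order]
    if len(x) < 3:
        raise DegenerateCurveError("elbow detection needs >= 3 curve points")
    x1, y1, xn, yn = x[0], y[0], x[-1], y[-1]
    denom = float(np.hypot(yn - y1, xn - x1))
    d = np.abs((yn - y1) * x - (xn - x1) * y + xn * y1 - yn * x1) / denom
    if np.allclose(d, 0.0):
        warnings.warn("find_elbow: curve is collinear; returning the sparsest point")
        return int(x[0])
    # ties -> smallest gene count; x is sorted ascending so take first argmax
    return int(x[int(np.argmax(d == np.max(d)))])


def select_gene_panel(
    ds: SCDataset,
    cell_type: str,
    k: int = 5,
    cfg: GeneSelectionConfig | None = None,
    seed: int | None = None,
) -> GenePanel:
    """Full panel selection for one cell type.

    Computes the CV accuracy curve, picks the panel size at its elbow, then
    ranks genes by elimination order on *all* cells of the type and returns
    the top genes. The panel is flagged low-confidence when the curve never
    reaches ``cfg.low_confidence_accuracy``.
    """
    cfg = cfg or GeneSelectionConfig(k_folds=k)
    if seed is not None:
        from dataclasses import replace as _rep

        cfg = _rep(cfg, seed=seed)
    sub = subset(ds, cell_types={cell_type})
    curve = cv_accuracy_curve(sub, k=k, cfg=cfg)
    n_opt = find_elbow(curve)
    X, _, _ = _standardize(sub.dense())
    rank = svm_rfe_rank(
        X,
        sub.condition,
        None,
        cfg.elimination_fraction,
        cfg.svm_c,
        cfg.max_iter,
    )
    order = np.argsort(rank)
    genes = [str(g) for g in sub.gene_ids[order[:n_opt]]]
    return GenePanel(
        genes=genes,
        n_selected=n_opt,
        source_cell_type=cell_type,
        low_confidence=bool(curve.mean_accuracy.max() < cfg.low_confidence_accuracy),
        curve=curve,
    )


def aggregate_stable_panels(
    panels: list[list[str]],
    ranks: list[dict[str, int]] | None = None,
    freq_threshold: float = 0.5,
) -> tuple[list[str], dict[str, float]]:
    """Combine per-subset panels: keep genes with frequency strictly above
    ``freq_threshold``, ordered by frequency (desc) then mean rank (asc)."""
    n = len(panels)
    count: dict[str, int] = {}
    for panel in panels:
        for g in panel:
            count[g] = count.get(g, 0) + 1
    freq = {g: c / n for g, c in count.items()}
    mean_rank: dict[str, float] = {}
    for g in freq:
        rs = []
        for i, panel in enumerate(panels):
            if g in panel:
                rs.append(ranks[i][g] if ranks else panel.index(g) + 1)
        mean_rank[g] = float(np.mean(rs))
    kept = [g for g, f in freq.items() if f > freq_threshold]
    kept.sort(key=lambda g: (-freq[g], mean_rank[g], g))
    return kept, freq


def stable_gene_panel(
    ds: SCDataset,
    cell_type: str,
    n_subsets: int = 20,
    subsample_fraction: float = 0.8,
    freq_threshold: float = 0.5,
    k: int = 5,
    cfg: GeneSelectionConfig | None = None,
    seed: int = 0,
) -> GenePanel:
    """Stability-selected panel over patient-level cohort downsamples.

    Each subset keeps ``subsample_fraction`` of the patients per condition
    (without replacement within a subset) and runs the standard selection;
    genes selected in strictly more than ``freq_threshold`` of the subsets
    form the final panel. When a condition has too few patients to
    downsample, cell-level downsampling is used instead with a warning.
    """
    cfg = cfg or GeneSelectionConfig(k_folds=k)
    sub = subset(ds, cell_types={cell_type})
    labels = sub.patient_condition()
    ss = np.random.SeedSequence(seed)
    subset_seeds = ss.generate_state(n_subsets)
    panels: list[list[str]] = []
    for i in range(n_subsets):
        rng = np.random.default_rng(int(subset_seeds[i]))
        chosen: list[str] = []
        feasible = True
        for cond in (0, 1):
            pats = sorted(p for p, c in labels.items() if c == cond)
            n_keep = max(2, int(round(subsample_fraction * len(pats))))
            if n_keep > len(pats):
                feasible = False
                break
            chosen.extend(pats[j] for j in rng.permutation(len(pats))[:n_keep])
        if feasible:
            ds_i = subset(sub, patients=chosen)
        else:
            warnings.warn(
                "stable_gene_panel: too few patients for patient-level "
                "downsampling; falling back to cell-level"
            )
            n_cells = max(10, int(round(subsample_fraction * sub.n_cells)))
            idx = rng.choice(sub.n_cells, size=min(n_cells, sub.n_cells), replace=False)
            ds_i = sub.take_cells(np.sort(idx))
        panel_i = select_gene_panel(
            ds_i, cell_type, k=k, cfg=cfg, seed=int(subset_seeds[i]) % (2**31)
        )
        panels.append(panel_i.genes)
    kept, freq = aggregate_stable_panels(panels, freq_threshold=freq_threshold)
    return GenePanel(
        genes=kept,
        n_selected=len(kept),
        source_cell_type=cell_type,
        selection_frequency=freq,
        subset_panels=panels,
    )
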