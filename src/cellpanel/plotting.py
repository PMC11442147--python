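"""Matplotlib figures: the parsimony curve and per-patient violin plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import CellPredictions, PatientReport
from .genes import RFECurve

__all__ = ["plot_parsimony", "plot_patient_violins"]


def plot_parsimony(curve: RFECurve, n_opt: int, path) -> Path:
    """Accuracy vs panel size with the chosen gene count marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    order = np.argsort(curve.gene_counts)
    x = np.asarray(curve.gene_counts)[order]
    m = np.asarray(curve.mean_accuracy)[order]
    s = np.asarray(curve.sd_accuracy)[order]
    ax.plot(x, m, lw=1.5, color="tab:blue")
    ax.fill_between(x, m - s, m + s, alpha=0.2, color="tab:blue")
    ax.axvline(n_opt, ls="--", color="tab:red", label=f"n = {n_opt}")
    ax.set_xlabel("genes retained")
    ax.set_ylabel(f"balanced accuracy ({curve.k_folds}-fold CV)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_patient_violins(preds: CellPredictions, report: PatientReport, path) -> Path:
    """Per-patient distribution of consensus cell probabilities.

    Patients are sorted by their AUC score; the dashed line marks the 0.5
    decision reference; the annotation above each violin is the patient's
    AUC with its bootstrap p-value.
    """
    df = report.per_patient.sort_values("auc")
    pats = df.index.tolist()
    data = [preds.consensus[preds.patient == p] for p in pats]
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(pats)), 4))
    parts = ax.violinplot(data, showmedians=True)
    cmap = {0: "tab:blue", 1: "tab:red"}
    for body, p in zip(parts["bodies"], pats):
        t = df.loc[p, "true_label"]
        body.set_facecolor(cmap.get(t, "gray"))
    for i, p in enumerate(pats):
        ax.annotate(
            f"{df.loc[p, 'auc']:.2f}\np={df.loc[p, 'p_value']:.3g}",
            (i + 1, 1.02), ha="center", fontsize=7, annotation_clip=False,
        )
    ax.axhline(0.5, ls="--", color="k", lw=0.8)
    ax.set_xticks(range(1, len(pats) + 1), pats, rotation=90, fontsize=7)
    ax.set_ylabel("consensus probability (perturbed)")
    ax.set_ylim(-0.02, 1.1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
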