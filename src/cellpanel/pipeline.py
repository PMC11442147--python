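"""End-to-end orchestration: normalize -> filter -> split -> rank cell
types -> select genes -> train ensemble -> classify held-out patients.

Two entry points: :func:`analyze` works on an in-memory dataset and
returns a :class:`PipelineResult`; :func:`run_pipeline` reads a config,
loads data, runs :func:`analyze` and writes every artifact into a
hash-stamped run directory so re-running with a changed config never
clobbers a previous run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cpio
from .celltype import ResponsivenessConfig, ResponsivenessTable, rank_cell_types
from .classify import (
    EnsembleConfig,
    PatientReport,
    classify_patients,
    predict_cells,
    train_ensemble,
)
from .data import SCDataset, SplitSpec, split_by_patient, subset
from .exceptions import CellPanelError
from .genes import GenePanel, GeneSelectionConfig, select_gene_panel, stable_gene_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "analyze", "run_pipeline",
           "downsample_experiment"]


@dataclass
class PipelineConfig:
    """One config to drive the whole pipeline (YAML-serializable)."""

    input_path: str = ""
    input_format: str | None = None
    patient_key: str = "patient"
    condition_key: str = "condition"
    celltype_key: str = "cell_type"
    positive_label: str = "1"
    seed: int = 0
    test_fraction: float = 0.2
    min_cells: int = 20
    min_patients: int = 3
    n_top_types: int = 1
    stable: bool = False
    stable_n_subsets: int = 20
    stable_subsample_fraction: float = 0.8
    stable_freq_threshold: float = 0.5
    k_folds: int = 5
    elimination_fraction: float = 0.03
    n_repeats: int = 20
    cells_per_patient: int = 20
    bootstrap_B: int = 1000
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise CellPanelError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    responsiveness: ResponsivenessTable
    selected_cell_type: str
    panel: GenePanel
    split: SplitSpec
    report: PatientReport


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["split", "celltype", "genes", "ensemble", "bootstrap"]
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def analyze(
    ds: SCDataset,
    seed: int = 0,
    test_fraction: float = 0.2,
    min_cells: int = 20,
    min_patients: int = 3,
    celltype_cfg: ResponsivenessConfig | None = None,
    genes_cfg: GeneSelectionConfig | None = None,
    ensemble_cfg: EnsembleConfig | None = None,
    k_folds: int = 5,
    stable: bool = False,
    stable_kwargs: dict | None = None,
    bootstrap_B: int = 1000,
) -> PipelineResult:
    """Run the complete analysis on an in-memory cohort.

    All stage randomness derives from ``seed`` via named substreams, so a
    run is reproducible end to end.
    """
    seeds = _stage_seeds(seed)
    if not ds.normalized and ds.layer == "raw":
        ds = cpio.normalize_counts(ds)
    ds = cpio.filter_cell_types(ds, min_cells=min_cells, min_patients=min_patients)
    split = split_by_patient(ds, test_fraction=test_fraction, seed=seeds["split"])
    train = subset(ds, patients=split.train_patients)
    # no patient may appear on both sides -- asserted on every run
    assert not (set(train.patient) & set(split.test_patients))

    ct_cfg = celltype_cfg or ResponsivenessConfig()
    ct_cfg = dataclasses.replace(ct_cfg, seed=seeds["celltype"])
    table = rank_cell_types(train, ct_cfg)
    cell_type = table.top(1)[0]

    g_cfg = genes_cfg or GeneSelectionConfig(k_folds=k_folds)
    if stable:
        panel = stable_gene_panel(
            train, cell_type, k=k_folds, cfg=g_cfg, seed=seeds["genes"],
            **(stable_kwargs or {}),
        )
    else:
        panel = select_gene_panel(
            train, cell_type, k=k_folds, cfg=g_cfg, seed=seeds["genes"]
        )

    train_ct = subset(train, cell_types={cell_type}, genes=panel.genes)
    model = train_ensemble(train_ct, seed=seeds["ensemble"], cfg=ensemble_cfg)
    test = subset(ds, patients=split.test_patients, cell_types={cell_type})
    preds = predict_cells(model, test)
    report = classify_patients(preds, B=bootstrap_B, seed=seeds["bootstrap"])
    return PipelineResult(
        responsiveness=table,
        selected_cell_type=cell_type,
        panel=panel,
        split=split,
        report=report,
    )


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Load data per config, run :func:`analyze`, write artifacts.

    Returns the run directory, named with the config hash; an existing
    directory for a different config is never overwritten.
    """
    run_dir = Path(cfg.output_dir) / f"run_{cfg.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "pipeline.log"
    handler = logging.FileHandler(log_path)
    logging.getLogger("cellpanel").addHandler(handler)
    stage = "setup"
    try:
        with open(run_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
        stage = "load"
        ds = cpio.load_dataset(
            cfg.input_path,
            format=cfg.input_format,
            patient_key=cfg.patient_key,
            condition_key=cfg.condition_key,
            celltype_key=cfg.celltype_key,
            positive_label=cfg.positive_label,
        )
        stage = "analyze"
        result = analyze(
            ds,
            seed=cfg.seed,
            test_fraction=cfg.test_fraction,
            min_cells=cfg.min_cells,
            min_patients=cfg.min_patients,
            celltype_cfg=ResponsivenessConfig(
                n_repeats=cfg.n_repeats, cells_per_patient=cfg.cells_per_patient
            ),
            genes_cfg=GeneSelectionConfig(
                k_folds=cfg.k_folds, elimination_fraction=cfg.elimination_fraction
            ),
            k_folds=cfg.k_folds,
            stable=cfg.stable,
            stable_kwargs=dict(
                n_subsets=cfg.stable_n_subsets,
                subsample_fraction=cfg.stable_subsample_fraction,
                freq_threshold=cfg.stable_freq_threshold,
            ),
            bootstrap_B=cfg.bootstrap_B,
        )
        stage = "write"
        _write_artifacts(result, run_dir, cfg)
    except CellPanelError as exc:
        # abort with the stage name; artifacts so far stay in run_dir
        (run_dir / "FAILED").write_text(
            f"stage: {stage}\n{type(exc).__name__}: {exc}\n"
        )
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise
    finally:
        logging.getLogger("cellpanel").removeHandler(handler)
        handler.close()
    return run_dir


def _write_artifacts(result: PipelineResult, run_dir: Path, cfg: PipelineConfig):
    stamp = {"config_hash": cfg.config_hash()}
    result.responsiveness.to_frame().to_csv(run_dir / "responsiveness.tsv", sep="\t")
    panel_payload = {
        **stamp,
        "cell_type": result.selected_cell_type,
        "genes": result.panel.genes,
        "n_selected": result.panel.n_selected,
        "low_confidence": result.panel.low_confidence,
        "selection_frequency": result.panel.selection_frequency,
    }
    (run_dir / "panel.json").write_text(json.dumps(panel_payload, indent=2))
    if result.panel.curve is not None:
        result.panel.curve.to_frame().to_csv(
            run_dir / "curve.tsv", sep="\t", index=False
        )
        try:
            from .plotting import plot_parsimony

            plot_parsimony(
                result.panel.curve,
                result.panel.n_selected,
                run_dir / "parsimony.png",
            )
        except Exception:  # plotting must never fail a run
            logger.exception("parsimony plot failed")
    report_payload = {
        **stamp,
        "per_patient": json.loads(result.report.per_patient.to_json(orient="index")),
        "metrics": result.report.metrics,
        "train_patients": sorted(result.split.train_patients),
        "test_patients": sorted(result.split.test_patients),
    }
    (run_dir / "patient_report.json").write_text(json.dumps(report_payload, indent=2))
    if result.report.metrics is not None:
        (run_dir / "metrics.json").write_text(
            json.dumps({**stamp, **result.report.metrics}, indent=2)
        )


def downsample_experiment(
    ds: SCDataset,
    fractions: list[float],
    seeds: list[int],
    axis: str = "patients",
    **analyze_kwargs,
):
    """Empirical power analysis: rerun cell-type and gene selection on
    downsampled cohorts and compare against the full-cohort run.

    Returns a DataFrame with one row per fraction x seed holding the
    rank-1 cell type, panel size and panel Jaccard similarity to the
    full-data panel. Infeasible fractions are marked skipped.
    """
    import pandas as pd

    if axis not in ("patients", "cells"):
        raise CellPanelError("axis must be 'patients' or 'cells'")
    base = _celltype_and_genes(ds, seed=seeds[0], **analyze_kwargs)
    rows = []
    for frac in fractions:
        for seed in seeds:
            if frac >= 1.0:
                sub_ds = ds
            else:
                rng = np.random.default_rng([seed, int(frac * 1000)])
                if axis == "patients":
                    labels = ds.patient_condition()
                    chosen = []
                    feasible = True
                    for cond in (0, 1):
                        pats = sorted(p for p, c in labels.items() if c == cond)
                        n_keep = int(round(frac * len(pats)))
                        if n_keep < 2:
                            feasible = False
                            break
                        chosen.extend(
                            pats[i] for i in rng.permutation(len(pats))[:n_keep]
                        )
                    if not feasible:
                        rows.append(
                            {"fraction": frac, "seed": seed, "skipped": True}
                        )
                        continue
                    sub_ds = subset(ds, patients=chosen)
                else:
                    n_keep = int(round(frac * ds.n_cells))
                    idx = rng.choice(ds.n_cells, size=n_keep, replace=False)
                    sub_ds = ds.take_cells(np.sort(idx))
            try:
                res = _celltype_and_genes(sub_ds, seed=seed, **analyze_kwargs)
            except CellPanelError:
                rows.append({"fraction": frac, "seed": seed, "skipped": True})
                continue
            a, b = set(res["panel"]), set(base["panel"])
            jac = len(a & b) / len(a | b) if (a | b) else 1.0
            rows.append(
                {
                    "fraction": frac,
                    "seed": seed,
                    "skipped": False,
                    "top_cell_type": res["cell_type"],
                    "panel_size": len(res["panel"]),
                    "jaccard_vs_full": jac,
                }
            )
    return pd.DataFrame(rows)


def _celltype_and_genes(ds: SCDataset, seed: int = 0, **kwargs) -> dict:
    seeds = _stage_seeds(seed)
    if not ds.normalized and ds.layer == "raw":
        ds = cpio.normalize_counts(ds)
    ds = cpio.filter_cell_types(
        ds,
        min_cells=kwargs.get("min_cells", 20),
        min_patients=kwargs.get("min_patients", 3),
    )
    cfg = kwargs.get("celltype_cfg") or ResponsivenessConfig()
    cfg = dataclasses.replace(cfg, seed=seeds["celltype"])
    table = rank_cell_types(ds, cfg)
    ct = table.top(1)[0]
    panel = select_gene_panel(
        ds, ct, k=kwargs.get("k_folds", 5),
        cfg=kwargs.get("genes_cfg"), seed=seeds["genes"],
    )
    return {"cell_type": ct, "panel": panel.genes, "table": table}
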