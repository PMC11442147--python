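"""Seeded synthetic scRNA-seq cohorts with a known responsive cell type.

The generative model is deliberately simple but captures the structure the
pipeline must cope with: negative-binomial counts with log-normal gene
means, gene-specific multiplicative per-donor random effects (the source
of donor-identity leakage that patient-wise splitting guards against),
per-cell library-size variation, and a
multiplicative fold change on a set of marker genes restricted to one
"responsive" cell type in perturbed patients only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SCDataset
from .exceptions import ConfigError, UnknownIdError

__all__ = ["SimConfig", "GroundTruth", "simulate_dataset", "make_fixture"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``log2_fold_change`` multiplies the mean of marker genes by
    ``2**log2_fold_change`` in cells of the responsive type belonging to
    perturbed patients. ``dispersion`` is the negative-binomial size
    parameter (inverse dispersion): smaller = more overdispersed.
    ``patient_effect_sd`` / ``library_size_sd`` are log-scale SDs of the
    multiplicative per-patient-per-gene and per-cell factors.
    """

    n_patients_per_class: int | tuple[int, int] = 10
    n_cell_types: int = 3
    cells_per_patient_per_type: int | tuple[int, int] = 60
    n_genes: int = 300
    n_marker_genes: int = 12
    responsive_cell_type_index: int = 0
    log2_fold_change: float = 2.0
    baseline_mean_log: tuple[float, float] = (-0.7, 1.0)
    dispersion: float = 2.0
    patient_effect_sd: float = 0.3
    library_size_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        n_ref, n_pert = self._class_sizes()
        if self.n_genes < 1 or n_ref < 1 or n_pert < 1 or self.n_cell_types < 1:
            raise ConfigError("n_genes, patients per class and n_cell_types must be >= 1")
        if not (0 <= self.n_marker_genes < self.n_genes):
            raise ConfigError("need 0 <= n_marker_genes < n_genes")
        if not (0 <= self.responsive_cell_type_index < self.n_cell_types):
            raise ConfigError("responsive_cell_type_index out of range")
        if self.log2_fold_change < 0:
            raise ConfigError("log2_fold_change must be >= 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")

    def _class_sizes(self) -> tuple[int, int]:
        if isinstance(self.n_patients_per_class, tuple):
            return self.n_patients_per_class
        return (self.n_patients_per_class, self.n_patients_per_class)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: the responsive type and its markers."""

    responsive_cell_type: str
    marker_genes: frozenset
    patient_labels: dict


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with given mean and NB size (inverse dispersion)."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_dataset(cfg: SimConfig) -> tuple[SCDataset, GroundTruth]:
    """Draw one cohort; byte-identical for identical configs (seed included)."""
    rng = np.random.default_rng(cfg.seed)
    mu, sigma = cfg.baseline_mean_log
    base_means = rng.lognormal(mu, sigma, size=cfg.n_genes)

    gene_ids = np.array([f"G{j:04d}" for j in range(cfg.n_genes)])
    marker_idx = rng.choice(cfg.n_genes, size=cfg.n_marker_genes, replace=False)
    # markers are drawn from the upper half of the baseline distribution:
    # candidate biomarkers must be expressed at detectable levels
    base_means[marker_idx] = np.exp(mu + sigma * np.abs(rng.standard_normal(cfg.n_marker_genes)))

    n_ref, n_pert = cfg._class_sizes()
    patients = [f"P{i:03d}" for i in range(n_ref + n_pert)]
    conditions = np.array([0] * n_ref + [1] * n_pert, dtype=np.int8)
    # gene-specific per-donor effects: a scalar per patient would be
    # degenerate with library size and vanish under depth normalization
    patient_effect = np.exp(
        rng.normal(0.0, cfg.patient_effect_sd, size=(len(patients), cfg.n_genes))
    )

    cell_types = [f"type_{t}" for t in range(cfg.n_cell_types)]
    responsive = cell_types[cfg.responsive_cell_type_index]
    # mild cell-type identity: each type scales a random third of genes
    type_profiles = np.ones((cfg.n_cell_types, cfg.n_genes))
    for t in range(cfg.n_cell_types):
        idx = rng.choice(cfg.n_genes, size=cfg.n_genes // 3, replace=False)
        type_profiles[t, idx] = np.exp(rng.normal(0.0, 0.5, size=len(idx)))

    fc = np.ones(cfg.n_genes)
    fc[marker_idx] = 2.0 ** cfg.log2_fold_change

    blocks, cell_ids, pats, conds, cts = [], [], [], [], []
    cell_counter = 0
    for pi, pat in enumerate(patients):
        for t, ct in enumerate(cell_types):
            if isinstance(cfg.cells_per_patient_per_type, tuple):
                lo, hi = cfg.cells_per_patient_per_type
                n_c = int(rng.integers(lo, hi + 1))
            else:
                n_c = int(cfg.cells_per_patient_per_type)
            lib = np.exp(rng.normal(0.0, cfg.library_size_sd, size=n_c))
            mean = base_means * type_profiles[t] * patient_effect[pi]
            if conditions[pi] == 1 and ct == responsive:
                mean = mean * fc
            mean_mat = lib[:, None] * mean[None, :]
            blocks.append(_nb_sample(rng, mean_mat, cfg.dispersion))
            cell_ids.extend(
                f"C{cell_counter + i:06d}" for i in range(n_c)
            )
            cell_counter += n_c
            pats.extend([pat] * n_c)
            conds.extend([conditions[pi]] * n_c)
            cts.extend([ct] * n_c)

    ds = SCDataset(
        counts=np.vstack(blocks).astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=np.array(cell_ids),
        patient=np.array(pats),
        condition=np.array(conds, dtype=np.int8),
        cell_type=np.array(cts),
    )
    markers = (
        frozenset(gene_ids[marker_idx]) if cfg.log2_fold_change > 0 else frozenset()
    )
    truth = GroundTruth(
        responsive_cell_type=responsive,
        marker_genes=markers,
        patient_labels={p: int(c) for p, c in zip(patients, conditions)},
    )
    return ds, truth


#: Preset cohorts used throughout the test suite.
_PRESETS: dict[str, SimConfig] = {
    # small & fast: unit-test scale
    "tiny": SimConfig(
        n_patients_per_class=4,
        n_cell_types=2,
        cells_per_patient_per_type=15,
        n_genes=60,
        n_marker_genes=8,
        log2_fold_change=2.0,
    ),
    # the study conditions: clear signal in one of three types
    "strong": SimConfig(),
    # identical structure, zero effect
    "null": SimConfig(log2_fold_change=0.0),
    # 3:1 patient class imbalance to exercise minority-class weighting
    "imbalanced": SimConfig(n_patients_per_class=(15, 5)),
}


def make_fixture(name: str, seed: int = 0) -> tuple[SCDataset, GroundTruth]:
    """Instantiate a named preset cohort with the given seed."""
    if name not in _PRESETS:
        raise UnknownIdError(
            f"unknown fixture {name!r}; choose from {sorted(_PRESETS)}"
        )
    from dataclasses import replace

    return simulate_dataset(replace(_PRESETS[name], seed=seed))
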