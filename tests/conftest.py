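import numpy as np
import pytest
from hypothesis import settings

import cellpanel as cp

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tiny():
    """Small synthetic cohort with known markers (normalized)."""
    ds, truth = cp.make_fixture("tiny", seed=7)
    return cp.normalize_counts(ds), truth


@pytest.fixture(scope="session")
def tiny_raw():
    ds, truth = cp.make_fixture("tiny", seed=7)
    return ds, truth


def make_labeled_dataset(
    cells_per_patient: dict, cell_type: str = "T", n_genes: int = 5, seed: int = 0
) -> cp.SCDataset:
    """Hand-rolled dataset builder: {patient: (condition, n_cells)}."""
    rng = np.random.default_rng(seed)
    pats, conds = [], []
    for p, (c, n) in cells_per_patient.items():
        pats.extend([p] * n)
        conds.extend([c] * n)
    n_cells = len(pats)
    return cp.SCDataset(
        counts=rng.poisson(2.0, size=(n_cells, n_genes)),
        gene_ids=[f"g{j}" for j in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        patient=pats,
        condition=np.array(conds),
        cell_type=[cell_type] * n_cells,
    )
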