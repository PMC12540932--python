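import anndata as ad
import numpy as np
import pandas as pd
import pytest

from scexplain import core_data, synthetic
from scexplain.core_data import CellMatrix


def make_cell_matrix(counts, subjects=None, conditions=None, cell_types=None,
                     dataset_id="d0", gene_ids=None, cell_ids=None) -> CellMatrix:
    """Hand-build a CellMatrix from explicit counts and metadata."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame({
        "subject_id": subjects if subjects is not None else [f"s{i}" for i in range(n)],
        "condition": conditions if conditions is not None else ["case"] * (n // 2) + ["control"] * (n - n // 2),
        "cell_type": cell_types if cell_types is not None else ["t0"] * n,
        "dataset_id": [dataset_id] * n,
    }, index=pd.Index(cell_ids if cell_ids is not None else [f"c{i}" for i in range(n)],
                      name="cell_id"))
    var = pd.DataFrame(index=pd.Index(
        gene_ids if gene_ids is not None else [f"g{j}" for j in range(g)],
        name="gene_id"))
    return CellMatrix(ad.AnnData(X=counts, obs=obs, var=var))


@pytest.fixture
def tiny_matrix() -> CellMatrix:
    """6 cells x 4 genes, 2 subjects per condition, deterministic counts."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 8, size=(6, 4))
    return make_cell_matrix(
        counts,
        subjects=["sA", "sA", "sB", "sC", "sC", "sD"],
        conditions=["case", "case", "case", "control", "control", "control"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-signal study: 3+3 subjects x 60 cells, 300 genes,
    10 signal genes at log2 effect 1.5; normalized. Shared session-wide."""
    cfg = synthetic.SimulationConfig(
        n_case_subjects=3, n_control_subjects=3, cells_per_subject=60,
        n_genes=300, n_signal_genes=10, signal_log2_effect=1.5, seed=7,
    )
    m, truth = synthetic.simulate_counts(cfg)
    return core_data.normalize_log(m), truth
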