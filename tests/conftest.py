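import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scdyn import synthetic_data as sd
from scdyn.labeled_io import LabeledExpressionMatrix


@pytest.fixture
def tiny_matrix() -> LabeledExpressionMatrix:
    """4 genes x 3 cells with hand-checkable counts.

    new = [[2, 0, 1], [3, 0, 0], [0, 0, 4], [0, 0, 0]]
    old = [[5, 1, 0], [0, 2, 0], [1, 0, 6], [0, 0, 0]]
    cell c0: new 5, old 6 -> NTR 5/11; c1: 0/3; c2: 5/11.
    """
    new = np.array([[2, 0, 1], [3, 0, 0], [0, 0, 4], [0, 0, 0]])
    old = np.array([[5, 1, 0], [0, 2, 0], [1, 0, 6], [0, 0, 0]])
    cells = pd.Index(["c0", "c1", "c2"], name="cell_id")
    return LabeledExpressionMatrix(
        gene_ids=pd.Index(["gA", "gB", "gC", "gD"]),
        cell_ids=cells,
        new_counts=sp.csr_matrix(new),
        old_counts=sp.csr_matrix(old),
        cell_annotations=pd.DataFrame(
            {"group": ["x", "x", "y"], "cluster": ["0", "1", "1"]}, index=cells
        ),
    )


@pytest.fixture(scope="session")
def dyn_small():
    """Small labeled-counts draw shared across read-only tests."""
    params = sd.DynGenParams(
        n_genes=250, n_cells_per_group=60, baseline_ntr=0.4, seed=11
    )
    return sd.generate_labeled_counts(params)


@pytest.fixture(scope="session")
def cohort_small():
    """Small cohort draw shared across read-only tests."""
    params = sd.CohortGenParams(n_genes=400, n_cells_per_group=80, seed=7)
    return sd.generate_lymphnode_cohort(params)
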