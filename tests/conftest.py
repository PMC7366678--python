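import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lungregen.core import CellTable
from lungregen.synthetic import SimConfig, simulate_timecourse


@pytest.fixture(scope="session")
def small_sim():
    """Small labeled time course with planted truth, shared across tests."""
    cfg = SimConfig(
        n_celltypes=4,
        n_genes=300,
        cells_per_sample=120,
        markers_per_celltype=8,
        ambient_gene_count=15,
        temporal_gene_count=5,
        seed=3,
    )
    table, truth = simulate_timecourse(cfg)
    return cfg, table, truth


@pytest.fixture()
def tiny_table():
    """Hand-built 4-cell x 3-gene table with layers."""
    counts = sp.csr_matrix(
        np.array([[1, 0, 2], [0, 3, 0], [4, 0, 0], [1, 1, 1]])
    )
    obs = pd.DataFrame(
        {
            "sample": ["s1", "s1", "s2", "s2"],
            "time_days": [0.0, 0.0, 14.0, 14.0],
            "label": ["A", "B", "A", "B"],
        }
    )
    return CellTable(
        counts=counts,
        gene_ids=np.array(["g1", "g2", "mt-g3"], dtype=object),
        cell_ids=np.array(["c1", "c2", "c3", "c4"], dtype=object),
        obs=obs,
        layers={
            "spliced": counts.copy(),
            "unspliced": sp.csr_matrix(np.array([[3, 0, 1], [0, 3, 0], [1, 0, 0], [0, 2, 1]])),
        },
    )
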