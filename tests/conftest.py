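import numpy as np
import pytest
import scipy.sparse as sp

from gficf.io_qc import RawCountMatrix
from gficf.simulate import SimConfig, simulate_counts, simulate_reference_panel


def make_counts(array, gene_ids=None, cell_ids=None) -> RawCountMatrix:
    """Wrap a dense integer array (genes x cells) as a RawCountMatrix."""
    array = np.asarray(array)
    n_genes, n_cells = array.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"c{j}" for j in range(n_cells)]
    return RawCountMatrix(sp.csc_matrix(array), np.array(gene_ids, dtype=object),
                          np.array(cell_ids, dtype=object))


def random_counts(rng, n_genes=15, n_cells=8, high=6) -> RawCountMatrix:
    """Random sparse-ish count matrix where every cell has depth > 0."""
    while True:
        arr = rng.integers(0, high, size=(n_genes, n_cells))
        arr[rng.random(arr.shape) < 0.4] = 0
        if (arr.sum(axis=0) > 0).all():
            return make_counts(arr)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset shared across tests (3 types x 80 cells)."""
    cfg = SimConfig(
        n_types=3, cells_per_type=80, n_genes=600, markers_per_type=15,
        depth_range=(700, 2000),  # scaled with the smaller gene universe
        seed=7,
    )
    m, labels, marker_map = simulate_counts(cfg)
    panel = simulate_reference_panel(
        marker_map, m.gene_ids, marker_fold=cfg.marker_fold, seed=11
    )
    return cfg, m, labels, marker_map, panel
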