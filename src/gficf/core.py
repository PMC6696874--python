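"""The gf-icf transform: TF-IDF weighting of UMI counts.

Treating each cell as a document and each gene as a word, the transform
weights gene *i* in cell *j* as

    GF_ij  = f_ij / sum_k f_kj          (per-cell proportion, sums to 1)
    ICF_i  = log(N / (n_i + 1))          (N cells, n_i cells expressing i)
    w_ij   = GF_ij * ICF_i,  then each cell column is L2-normalized.

GF removes sequencing-depth differences, ICF up-weights genes expressed
in few cells (the informative ones) and down-weights ubiquitous genes,
and the final L2 step makes cells directly comparable by inner product.

Two points the formula leaves open are exposed as options:

* ``icf_smoothing`` — the smoothing can sit inside the denominator,
  ``log(N/(n_i+1))`` (default, the standard smoothed IDF), or outside,
  ``log(N/n_i + 1)``.
* ``allow_negative_icf`` — under the default smoothing a gene expressed
  in every cell gets ICF ``log(N/(N+1)) < 0``.  By default such genes
  are clamped to 0 (a negative "importance" inverts the score's
  meaning); the literal formula is kept when the flag is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .io_qc import RawCountMatrix

__all__ = [
    "GficfMatrix",
    "gene_frequency",
    "inverse_cell_frequency",
    "gficf_transform",
    "write_gficf",
    "read_gficf",
]


@dataclass
class GficfMatrix:
    """Genes x cells gf-icf weights, each cell column of unit L2 norm.

    ``icf`` records the raw formula value per gene (before any
    clamping); ``clamped_genes`` marks genes whose negative ICF was
    clamped to zero.
    """

    weights: sp.csc_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    icf: np.ndarray
    n_cells_expressing: np.ndarray
    n_cells: int
    icf_smoothing: str = "add_one_denominator"
    clamped_genes: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]


def gene_frequency(m: RawCountMatrix) -> sp.csc_matrix:
    """Normalize each cell column to sum one (the GF step).

    Zeros and the sparsity pattern are preserved.  A cell with zero
    total count has no defined proportions and raises ``ValueError``.
    """
    totals = m.umi_per_cell()
    if np.any(totals == 0):
        bad = m.cell_ids[totals == 0]
        raise ValueError(f"all-zero cell column(s): {', '.join(map(str, bad[:5]))}")
    gf = m.counts.astype(np.float64).tocsc(copy=True)
    # scale each column by 1/total; operate on indptr-aligned data
    scale = np.repeat(1.0 / totals, np.diff(gf.indptr))
    gf.data *= scale
    return gf


def inverse_cell_frequency(
    m: RawCountMatrix, smoothing: str = "add_one_denominator"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene ICF weight and the per-gene expressing-cell count n_i.

    ``add_one_denominator`` gives ``log(N/(n_i+1))``;
    ``add_one_outside`` gives ``log(N/n_i + 1)`` (infinite for n_i = 0
    is avoided by treating an unexpressed gene as n_i+1 -> 1, i.e.
    ``log(N + 1)``).
    """
    n_i = m.cells_per_gene()
    n = m.n_cells
    if n < 1:
        raise ValueError("need at least one cell")
    if smoothing == "add_one_denominator":
        icf = np.log(n / (n_i + 1.0))
    elif smoothing == "add_one_outside":
        icf = np.log(n / np.maximum(n_i, 1.0) + 1.0)
    else:
        raise ValueError(f"unknown icf_smoothing: {smoothing!r}")
    return icf, n_i


def gficf_transform(
    m: RawCountMatrix,
    smoothing: str = "add_one_denominator",
    allow_negative_icf: bool = False,
) -> GficfMatrix:
    """GF x ICF weighting followed by per-cell L2 normalization."""
    gf = gene_frequency(m)
    icf, n_i = inverse_cell_frequency(m, smoothing)
    if allow_negative_icf:
        applied = icf
        clamped = np.zeros_like(icf, dtype=bool)
    else:
        applied = np.maximum(icf, 0.0)
        clamped = icf < 0.0

    w = sp.diags(applied) @ gf
    w = sp.csc_matrix(w)
    w.eliminate_zeros()
    norms = np.sqrt(np.asarray(w.multiply(w).sum(axis=0)).ravel())
    dead = norms == 0.0
    if np.any(dead):
        bad = m.cell_ids[dead]
        raise ValueError(
            "cell(s) with zero gf-icf weight on every expressed gene: "
            + ", ".join(map(str, bad[:5]))
        )
    w.data *= np.repeat(1.0 / norms, np.diff(w.indptr))
    return GficfMatrix(
        weights=w,
        gene_ids=m.gene_ids,
        cell_ids=m.cell_ids,
        icf=icf,
        n_cells_expressing=n_i,
        n_cells=m.n_cells,
        icf_smoothing=smoothing,
        clamped_genes=clamped,
    )


def write_gficf(g: GficfMatrix, out_dir) -> None:
    """Write weights as Matrix Market plus sidecar id lists and ICF table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out_dir / "gficf.mtx"), g.weights.tocoo(), precision=12)
    (out_dir / "gficf_genes.tsv").write_text(
        "".join(f"{x}\n" for x in g.gene_ids)
    )
    (out_dir / "gficf_barcodes.tsv").write_text(
        "".join(f"{x}\n" for x in g.cell_ids)
    )
    pd.DataFrame(
        {
            "gene_id": g.gene_ids,
            "n_cells_expressing": g.n_cells_expressing,
            "icf": g.icf,
        }
    ).to_csv(out_dir / "icf.tsv", sep="\t", index=False)


def read_gficf(out_dir) -> GficfMatrix:
    out_dir = Path(out_dir)
    w = sp.csc_matrix(mmread(str(out_dir / "gficf.mtx")))
    gene_ids = np.array(
        (out_dir / "gficf_genes.tsv").read_text().split(), dtype=object
    )
    cell_ids = np.array(
        (out_dir / "gficf_barcodes.tsv").read_text().split(), dtype=object
    )
    tab = pd.read_csv(out_dir / "icf.tsv", sep="\t")
    return GficfMatrix(
        weights=w,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        icf=tab["icf"].to_numpy(),
        n_cells_expressing=tab["n_cells_expressing"].to_numpy(),
        n_cells=len(cell_ids),
    )
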