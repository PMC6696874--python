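"""Reading, writing and quality control of UMI count matrices.

The count matrix convention throughout the package is genes as rows and
cells as columns, mirroring the 10x Genomics plain-text layout
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``).  Dense delimited
tables (gene rows, cell columns) are supported as a second format.

Quality control removes low-quality cells by three criteria evaluated
per cell barcode: number of detected genes, total UMI, and the fraction
of UMIs mapping to mitochondrial genes.  Cells are retained when

    n_genes >= min_genes  AND  n_umi >= min_umi  AND
    mito_umi / n_umi <= max_mito_fraction

so a cell sitting exactly on a threshold passes.  The gene set is never
changed by QC; genes that end up with zero total count are merely
flagged (downstream weighting handles unexpressed genes explicitly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "RawCountMatrix",
    "QcThresholds",
    "QcError",
    "NoCellsRetainedError",
    "read_counts",
    "write_counts",
    "qc_filter",
    "mito_genes_from_prefix",
    "DEFAULT_MITO_PREFIXES",
]

DEFAULT_MITO_PREFIXES = ("MT-", "mt-")


class QcError(ValueError):
    """Malformed count matrix input."""


class NoCellsRetainedError(RuntimeError):
    """Every cell failed the QC thresholds."""


@dataclass
class RawCountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts."""

    counts: sp.csc_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise QcError(
                f"matrix has {n_genes} gene rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise QcError(
                f"matrix has {n_cells} cell columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise QcError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n_cells:
            raise QcError("duplicate cell identifiers")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise QcError("negative count encountered")
            if not np.allclose(data, np.round(data)):
                raise QcError("non-integer count encountered")
        self.counts = self.counts.astype(np.int64)
        self.counts.eliminate_zeros()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def umi_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells expressing each gene (count > 0)."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def zero_count_genes(self) -> np.ndarray:
        """Ids of genes with zero total count (kept, but flagged)."""
        return self.gene_ids[self.cells_per_gene() == 0]

    def subset_cells(self, mask: np.ndarray) -> "RawCountMatrix":
        return RawCountMatrix(
            self.counts[:, mask], self.gene_ids, self.cell_ids[mask]
        )


@dataclass
class QcThresholds:
    """Cell-level QC cutoffs.

    Defaults follow the common droplet-data practice: at least 500
    detected genes, at least 1,500 total UMI, and at most 10% of UMIs on
    mitochondrial genes.
    """

    min_genes: int = 500
    min_umi: int = 1500
    max_mito_fraction: float = 0.10
    mito_gene_set: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.min_genes < 0 or self.min_umi < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        self.mito_gene_set = frozenset(self.mito_gene_set)


def mito_genes_from_prefix(
    gene_ids, prefixes=DEFAULT_MITO_PREFIXES
) -> frozenset:
    """Identify mitochondrial genes by id prefix (default ``MT-``/``mt-``)."""
    return frozenset(g for g in gene_ids if str(g).startswith(tuple(prefixes)))


def _read_id_list(path: Path) -> np.ndarray:
    """First column of a headerless TSV (10x genes.tsv carries id + symbol)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return np.asarray(ids, dtype=object)


def read_counts(
    path,
    format: str = "mtx_triplet",
    genes_path=None,
    barcodes_path=None,
) -> RawCountMatrix:
    """Read a genes x cells UMI count matrix.

    Parameters
    ----------
    path
        For ``mtx_triplet``: the ``matrix.mtx`` file or a directory
        containing ``matrix.mtx``, ``genes.tsv`` and ``barcodes.tsv``.
        For ``dense_table``: a TSV/CSV with a header row of cell ids and
        a first column of gene ids.
    format
        ``"mtx_triplet"`` or ``"dense_table"``.
    genes_path, barcodes_path
        Override the sidecar locations for ``mtx_triplet``.
    """
    path = Path(path)
    if format == "mtx_triplet":
        if path.is_dir():
            mtx = path / "matrix.mtx"
            genes_path = genes_path or path / "genes.tsv"
            barcodes_path = barcodes_path or path / "barcodes.tsv"
        else:
            mtx = path
            genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
            barcodes_path = (
                Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
            )
        for p in (mtx, genes_path, barcodes_path):
            if not Path(p).exists():
                raise QcError(f"missing input file: {p}")
        counts = sp.csc_matrix(mmread(str(mtx)))
        if counts.data.size and not np.allclose(counts.data, np.round(counts.data)):
            raise QcError("non-integer count in matrix file")
        gene_ids = _read_id_list(Path(genes_path))
        cell_ids = _read_id_list(Path(barcodes_path))
        return RawCountMatrix(counts, gene_ids, cell_ids)
    if format == "dense_table":
        if not path.exists():
            raise QcError(f"missing input file: {path}")
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy()
        if values.size and not np.allclose(
            values.astype(float), np.round(values.astype(float))
        ):
            raise QcError("non-integer count in dense table")
        return RawCountMatrix(
            sp.csc_matrix(values.astype(np.int64)),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
        )
    raise ValueError(f"unknown format: {format!r}")


def write_counts(m: RawCountMatrix, path, format: str = "mtx_triplet") -> None:
    """Write a count matrix in either supported format (exact round trip)."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), m.counts.tocoo(), field="integer")
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    elif format == "dense_table":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.DataFrame(
            m.counts.toarray(), index=m.gene_ids, columns=m.cell_ids
        )
        df.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format: {format!r}")


def qc_filter(
    m: RawCountMatrix, t: QcThresholds
) -> tuple[RawCountMatrix, pd.DataFrame]:
    """Filter cells by detected genes, total UMI and mitochondrial fraction.

    Returns the filtered matrix (same gene set, retained cells in input
    order) and a per-cell report with columns ``cell_id``, ``n_genes``,
    ``n_umi``, ``mito_fraction`` and ``pass``.

    Raises
    ------
    NoCellsRetainedError
        If no cell satisfies all three criteria.
    """
    mito_set = t.mito_gene_set
    absent = mito_set - set(m.gene_ids)
    if absent:
        warnings.warn(
            f"{len(absent)} mitochondrial gene(s) absent from the matrix",
            stacklevel=2,
        )
    mito_mask = np.isin(m.gene_ids.astype(str), [str(g) for g in mito_set])

    n_umi = m.umi_per_cell()
    n_genes = m.genes_per_cell()
    mito_umi = np.asarray(m.counts[mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)

    ok = (
        (n_genes >= t.min_genes)
        & (n_umi >= t.min_umi)
        & (mito_fraction <= t.max_mito_fraction)
    )
    report = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "n_genes": n_genes,
            "n_umi": n_umi,
            "mito_fraction": mito_fraction,
            "pass": ok,
        }
    )
    if not ok.any():
        raise NoCellsRetainedError("no cells retained by QC thresholds")
    return m.subset_cells(ok), report
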