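"""Synthetic scRNA-seq data with planted cell types.

Generates sparse, zero-inflated UMI count matrices that exercise every
stage of the pipeline: discrete cell types defined by marker genes,
per-cell sequencing depth drawn from a range, expression-dependent
dropout (the probability of zeroing an entry decays logistically with
its expected count, the standard zero-inflation structure), and a
dedicated block of mitochondrial genes (ids ``MT-1`` ...) whose
per-cell UMI share is controlled so QC's mitochondrial filter can be
exercised.  A matched bulk reference panel with the same gene
namespace supports end-to-end annotation tests.

Sampling is multinomial conditioned on the drawn per-cell depth, so
column sums are exactly controlled before dropout and the sum-to-one
GF step is exercised against known expected proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotate import ReferencePanel
from .io_qc import RawCountMatrix, write_counts

__all__ = ["SimConfig", "simulate_counts", "simulate_reference_panel", "write_simulation"]


@dataclass
class SimConfig:
    """Parameters of the synthetic count generator.

    Defaults describe a mid-sized droplet experiment: 5 cell types of
    200 cells, 2,000 genes of which 20 per type are markers expressed
    8-fold above baseline, depths of 2,500-7,500 UMIs, moderate
    expression-dependent dropout, and mitochondrial content between 1%
    and 8% of each cell's UMIs.
    """

    n_types: int = 5
    cells_per_type: int = 200
    n_genes: int = 2000
    markers_per_type: int = 20
    marker_fold: float = 8.0
    base_expression: np.ndarray | None = None   # per-gene rates; drawn log-normal if None
    base_log_sigma: float = 2.0
    depth_range: tuple = (2500, 7500)
    dropout_logit_slope: float = 1.0
    dropout_logit_intercept: float = -1.0
    mito_fraction_range: tuple = (0.01, 0.08)
    n_mito_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be positive")
        if self.n_types * self.markers_per_type > self.n_genes - self.n_mito_genes:
            raise ValueError("marker genes exceed available (non-mito) genes")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ValueError("depth_range must be well-ordered and positive")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("mito_fraction_range must be well-ordered in [0, 1)")


def _gene_ids(cfg: SimConfig) -> np.ndarray:
    n_nuc = cfg.n_genes - cfg.n_mito_genes
    width = len(str(n_nuc))
    ids = [f"G{i + 1:0{width}d}" for i in range(n_nuc)]
    ids += [f"MT-{i + 1}" for i in range(cfg.n_mito_genes)]
    return np.array(ids, dtype=object)


def simulate_counts(
    cfg: SimConfig,
) -> tuple[RawCountMatrix, np.ndarray, dict]:
    """Draw a genes x cells UMI matrix with planted types.

    Returns the count matrix, one true type label per cell, and the
    marker map (type -> list of marker gene ids).  Fully reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = _gene_ids(cfg)
    n_nuc = cfg.n_genes - cfg.n_mito_genes
    n_cells = cfg.n_types * cfg.cells_per_type

    if cfg.base_expression is not None:
        base = np.asarray(cfg.base_expression, dtype=float)
        if base.shape != (cfg.n_genes,) or np.any(base <= 0):
            raise ValueError("base_expression must be positive with one rate per gene")
    else:
        base = rng.lognormal(mean=0.0, sigma=cfg.base_log_sigma, size=cfg.n_genes)
    nuc_base = base[:n_nuc]
    mito_base = base[n_nuc:]

    # disjoint marker blocks among nuclear genes.  Markers are drawn from
    # the detectable-but-not-ubiquitous expression band: a near-silent
    # gene is never observed even fold-boosted, while a near-ubiquitous
    # one is a housekeeping gene (expressed in ~every cell its inverse
    # cell frequency is ~0, so by construction it cannot mark a type).
    lo, hi = np.quantile(nuc_base, [0.5, 0.9])
    candidates = np.flatnonzero((nuc_base >= lo) & (nuc_base < hi))
    n_markers = cfg.n_types * cfg.markers_per_type
    if n_markers > len(candidates):
        raise ValueError("marker genes exceed the eligible expression band")
    marker_idx = rng.choice(candidates, size=n_markers, replace=False)
    types = [f"type{t}" for t in range(cfg.n_types)]
    marker_map = {}
    type_props = np.empty((cfg.n_types, n_nuc))
    for t in range(cfg.n_types):
        idx = np.sort(marker_idx[t * cfg.markers_per_type:(t + 1) * cfg.markers_per_type])
        marker_map[types[t]] = [str(g) for g in gene_ids[idx]]
        rates = nuc_base.copy()
        rates[idx] *= cfg.marker_fold
        type_props[t] = rates / rates.sum()
    mito_props = mito_base / mito_base.sum()

    labels = np.repeat(types, cfg.cells_per_type)
    depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, size=n_cells)
    mito_f = rng.uniform(*cfg.mito_fraction_range, size=n_cells)

    cols = np.zeros((cfg.n_genes, n_cells), dtype=np.int64)
    for j in range(n_cells):
        t = j // cfg.cells_per_type
        mito_depth = int(round(mito_f[j] * depths[j]))
        nuc_depth = int(depths[j]) - mito_depth
        expected = np.concatenate(
            [nuc_depth * type_props[t], mito_depth * mito_props]
        )
        counts = np.concatenate(
            [
                rng.multinomial(nuc_depth, type_props[t]),
                rng.multinomial(mito_depth, mito_props),
            ]
        )
        p_drop = 1.0 / (
            1.0
            + np.exp(
                -(cfg.dropout_logit_intercept - cfg.dropout_logit_slope * np.log1p(expected))
            )
        )
        keep = rng.random(cfg.n_genes) >= p_drop
        dropped = counts * keep
        if dropped.sum() == 0:
            # a cell can never lose every transcript: restore its largest entry
            dropped[np.argmax(counts)] = counts.max()
        cols[:, j] = dropped

    width = len(str(n_cells))
    cell_ids = np.array(
        [f"cell{j + 1:0{width}d}" for j in range(n_cells)], dtype=object
    )
    m = RawCountMatrix(sp.csc_matrix(cols), gene_ids, cell_ids)
    return m, labels, marker_map


def simulate_reference_panel(
    marker_map: dict,
    gene_ids,
    n_samples_per_type: int = 3,
    noise_sd: float = 0.25,
    marker_fold: float = 8.0,
    base_expression: np.ndarray | None = None,
    seed: int = 0,
) -> ReferencePanel:
    """Bulk expression profiles of the planted types, same gene namespace.

    Each sample of type *t* expresses that type's markers
    ``marker_fold`` above baseline, with multiplicative log-normal
    noise; ``noise_sd`` 0 gives exact profiles whose log-fold-change
    ranking puts the markers at the very top.
    """
    rng = np.random.default_rng(seed)
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_genes = len(gene_ids)
    if base_expression is not None:
        base = np.asarray(base_expression, dtype=float)
    else:
        base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base = 100.0 * base  # bulk-like expression scale

    gene_pos = {str(g): i for i, g in enumerate(gene_ids)}
    cols, names, sample_types = [], [], []
    for t in sorted(marker_map):
        idx = np.array([gene_pos[g] for g in marker_map[t]], dtype=int)
        profile = base.copy()
        profile[idx] *= marker_fold
        for s in range(n_samples_per_type):
            noise = (
                rng.lognormal(mean=0.0, sigma=noise_sd, size=n_genes)
                if noise_sd > 0
                else 1.0
            )
            cols.append(profile * noise)
            names.append(f"{t}_s{s + 1}")
            sample_types.append(t)
    expr = pd.DataFrame(
        np.column_stack(cols), index=gene_ids.astype(str), columns=names
    )
    return ReferencePanel(
        expression=expr,
        sample_cell_type=np.array(sample_types, dtype=object),
        cell_types=np.unique(sample_types),
    )


def write_simulation(
    out_dir,
    m: RawCountMatrix,
    labels: np.ndarray,
    marker_map: dict,
    panel: ReferencePanel | None = None,
) -> None:
    """Write the fixture files in the formats the readers consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_counts(m, out_dir, format="mtx_triplet")
    pd.DataFrame({"cell_id": m.cell_ids, "cell_type": labels}).to_csv(
        out_dir / "truth_labels.tsv", sep="\t", index=False
    )
    rows = [
        {"cell_type": t, "gene_id": g}
        for t in sorted(marker_map)
        for g in marker_map[t]
    ]
    pd.DataFrame(rows).to_csv(out_dir / "marker_map.tsv", sep="\t", index=False)
    if panel is not None:
        panel.expression.to_csv(out_dir / "panel.tsv", sep="\t")
        pd.DataFrame(
            {
                "sample": panel.expression.columns,
                "cell_type": panel.sample_cell_type,
            }
        ).to_csv(out_dir / "panel_labels.tsv", sep="\t", index=False)
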