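"""Dimensionality reduction: PCA meta-genes and 2-D embedding.

Cells are observations, gf-icf weights are features.  The top 50
principal-component scores ("meta-genes") feed t-SNE (default,
perplexity 30, seed 0) or UMAP; final 2-D coordinates are rescaled
per axis to [-1, 1] before clustering and distance computations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .core import GficfMatrix

__all__ = ["MetaGeneMatrix", "Embedding", "pca_meta_genes", "embed", "rescale_coords"]


@dataclass
class MetaGeneMatrix:
    """Cells x components PCA scores with explained variances."""

    scores: np.ndarray
    explained_variance: np.ndarray
    cell_ids: np.ndarray
    n_components: int


@dataclass
class Embedding:
    """Cells x 2 coordinates from t-SNE or UMAP."""

    coords: np.ndarray
    cell_ids: np.ndarray
    method: str
    seed: int
    perplexity: float | None = None
    rescaled: bool = False


def pca_meta_genes(
    g: GficfMatrix, n_components: int = 50, seed: int = 0
) -> MetaGeneMatrix:
    """Project cells onto the top principal axes of the gf-icf weights.

    Features (genes) are mean-centered, not variance-scaled.  Component
    signs are fixed by forcing each component's largest-magnitude gene
    loading positive, so results do not depend on solver internals.
    """
    x = np.asarray(g.weights.T.todense(), dtype=np.float64)  # cells x genes
    n_cells, n_genes = x.shape
    max_comp = min(n_cells, n_genes) - 1
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds the admissible maximum "
            f"{max_comp} for a {n_cells} x {n_genes} matrix"
        )
    solver = "full" if min(n_cells, n_genes) <= 2000 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(x)
    # deterministic sign: largest |loading| of each component is positive
    flip = np.sign(
        pca.components_[
            np.arange(n_components), np.argmax(np.abs(pca.components_), axis=1)
        ]
    )
    flip[flip == 0] = 1.0
    scores *= flip
    return MetaGeneMatrix(
        scores=scores,
        explained_variance=pca.explained_variance_.copy(),
        cell_ids=g.cell_ids,
        n_components=n_components,
    )


def embed(
    mg: MetaGeneMatrix,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
) -> Embedding:
    """Embed cells in 2-D from their meta-gene scores.

    t-SNE and UMAP are delegated to scikit-learn and umap-learn; the
    seed pins their internal randomization so identical inputs give
    identical coordinates.
    """
    n = mg.scores.shape[0]
    if method == "tsne":
        if perplexity >= (n - 1) / 3:
            raise ValueError(
                f"perplexity {perplexity} too large for {n} cells "
                f"(needs < {(n - 1) / 3:.1f})"
            )
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
            n_jobs=1,
        )
        coords = tsne.fit_transform(mg.scores)
    elif method == "umap":
        import umap  # deferred: numba compilation is slow at import

        reducer = umap.UMAP(n_components=2, random_state=seed)
        coords = reducer.fit_transform(mg.scores)
    else:
        raise ValueError(f"unknown embedding method: {method!r}")
    return Embedding(
        coords=np.asarray(coords, dtype=np.float64),
        cell_ids=mg.cell_ids,
        method=method,
        seed=seed,
        perplexity=perplexity if method == "tsne" else None,
    )


def rescale_coords(e: Embedding) -> Embedding:
    """Min-max rescale each axis independently to [-1, 1].

    A degenerate axis (all values equal) maps to 0.  The map is linear
    and order-preserving per axis, and idempotent.
    """
    if e.coords.shape[0] < 2:
        raise ValueError("rescaling needs at least 2 cells")
    lo = e.coords.min(axis=0)
    hi = e.coords.max(axis=0)
    span = hi - lo
    out = np.zeros_like(e.coords)
    for ax in range(e.coords.shape[1]):
        if span[ax] > 0:
            out[:, ax] = 2.0 * (e.coords[:, ax] - lo[ax]) / span[ax] - 1.0
    return replace(e, coords=out, rescaled=True)
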