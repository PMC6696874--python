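"""PhenoGraph-style cell graph and Louvain community detection.

From embedded coordinates, each cell's k nearest neighbors (Manhattan
distance, self excluded, ties broken by ascending cell index) define a
neighbor set N_k.  An undirected edge joins u and v whenever one lies in
the other's neighbor set, weighted by the Jaccard coefficient of the two
k-sets,

    J(u, v) = |N_k(u) ∩ N_k(v)| / |N_k(u) ∪ N_k(v)|,

with zero-weight edges omitted.  Communities are found by Louvain
modularity maximization (igraph's multilevel algorithm); the graph
construction is bespoke, the community detection is delegated.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .embedding import Embedding

__all__ = ["CellGraph", "Clustering", "knn_graph", "louvain_cluster"]


@dataclass
class CellGraph:
    """Jaccard-weighted shared-neighbor graph over cells."""

    cell_ids: np.ndarray
    edges: np.ndarray       # (n_edges, 2) int, u < v
    weights: np.ndarray     # (n_edges,) Jaccard in (0, 1]
    neighbor_sets: list     # per cell, the k-NN index set (self excluded)
    k: int
    metric: str = "manhattan"

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class Clustering:
    """One cluster label per cell, ids contiguous from 0."""

    labels: np.ndarray
    cell_ids: np.ndarray
    n_clusters: int
    modularity: float


def _knn_indices(coords: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """k nearest neighbors per row under Manhattan distance.

    Self is excluded; distance ties are resolved by ascending index
    (stable argsort), so the neighbor sets are fully deterministic.
    Distances are computed in row chunks to bound memory.
    """
    n = coords.shape[0]
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = np.abs(
            coords[start:stop, None, :] - coords[None, :, :]
        ).sum(axis=2)
        block[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.argsort(block, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return out


def knn_graph(
    e: Embedding | np.ndarray, k: int = 50, metric: str = "manhattan"
) -> CellGraph:
    """Build the Jaccard-weighted k-nearest-neighbor graph of cells."""
    if metric != "manhattan":
        raise ValueError("only the manhattan metric is supported")
    if isinstance(e, Embedding):
        coords, cell_ids = e.coords, e.cell_ids
    else:
        coords = np.asarray(e, dtype=np.float64)
        cell_ids = np.arange(coords.shape[0])
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if not np.all(np.isfinite(coords)):
        raise ValueError("embedding coordinates must be finite")

    nbrs = _knn_indices(coords, k)
    nbr_sets = [frozenset(row.tolist()) for row in nbrs]

    seen = set()
    edges, weights = [], []
    for u in range(n):
        for v in nbrs[u]:
            a, b = (u, int(v)) if u < v else (int(v), u)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(nbr_sets[a] & nbr_sets[b])
            if inter:
                union = len(nbr_sets[a] | nbr_sets[b])
                edges.append((a, b))
                weights.append(inter / union)
    edges_arr = (
        np.array(sorted(edges), dtype=np.int64)
        if edges
        else np.empty((0, 2), dtype=np.int64)
    )
    if edges:
        order = {e: i for i, e in enumerate(edges)}
        weights_arr = np.array(
            [weights[order[tuple(e)]] for e in edges_arr.tolist()], dtype=np.float64
        )
    else:
        weights_arr = np.empty(0, dtype=np.float64)
    return CellGraph(
        cell_ids=np.asarray(cell_ids, dtype=object),
        edges=edges_arr,
        weights=weights_arr,
        neighbor_sets=nbr_sets,
        k=k,
        metric=metric,
    )


def louvain_cluster(g: CellGraph, seed: int = 0) -> Clustering:
    """Partition the cell graph with Louvain modularity maximization.

    Cells with no positive-Jaccard edge become singleton clusters.
    Labels are renumbered contiguously in order of first appearance by
    cell index, so the output is deterministic for a fixed seed.
    """
    n = g.n_cells
    if len(g.edges) == 0:
        warnings.warn("empty edge set: every cell becomes its own cluster")
        return Clustering(
            labels=np.arange(n),
            cell_ids=g.cell_ids,
            n_clusters=n,
            modularity=float("nan"),
        )
    graph = ig.Graph(n=n, edges=[tuple(e) for e in g.edges.tolist()])
    graph.es["weight"] = list(g.weights)
    random.seed(seed)  # igraph's python RNG hook
    part = graph.community_multilevel(weights="weight")
    raw = np.asarray(part.membership, dtype=np.int64)
    # contiguous relabeling by first occurrence
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    modularity = graph.modularity(list(raw), weights="weight")
    return Clustering(
        labels=labels,
        cell_ids=g.cell_ids,
        n_clusters=int(labels.max()) + 1,
        modularity=float(modularity),
    )
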