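"""External cluster-quality and annotation metrics.

Implements the Hubert-Arabie adjusted Rand index, cluster purity, the
mean within-type pairwise Euclidean distance on rescaled embedding
coordinates, and per-cell annotation accuracy.  Binomial coefficients
in the ARI use exact integer arithmetic, so contingency counts in the
tens of thousands cannot overflow or lose precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .embedding import Embedding

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "adjusted_rand_index",
    "purity",
    "intra_type_distance",
    "annotation_accuracy",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray        # clusters x classes, int
    row_labels: np.ndarray
    col_labels: np.ndarray


def contingency_table(labels_a, labels_b) -> ContingencyTable:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    rows, ai = np.unique(a, return_inverse=True)
    cols, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)
    return ContingencyTable(counts=counts, row_labels=rows, col_labels=cols)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie chance-corrected Rand index of two partitions.

    Returns 1 for identical partitions (up to relabeling); its expected
    value under independent random partitions is 0.
    """
    a = np.asarray(labels_a)
    if a.size < 2:
        raise ValueError("need at least 2 items")
    tab = contingency_table(labels_a, labels_b).counts
    n = int(tab.sum())
    sum_ij = sum(comb(int(x), 2) for x in tab.ravel())
    sum_a = sum(comb(int(x), 2) for x in tab.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in tab.sum(axis=0))
    pairs = comb(n, 2)
    expected = sum_a * sum_b / pairs
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0  # both partitions trivial and identical
    return float((sum_ij - expected) / (max_index - expected))


def purity(clusters, classes) -> float:
    """Fraction of cells in the majority ground-truth class of their cluster.

    (1/N) * sum over clusters of the largest cluster-class overlap;
    always in (0, 1], and 1 exactly when every cluster is class-pure.
    """
    tab = contingency_table(clusters, classes).counts
    n = tab.sum()
    if n == 0:
        raise ValueError("need at least 1 item")
    return float(tab.max(axis=1).sum() / n)


def intra_type_distance(
    e: Embedding | np.ndarray,
    classes,
    max_pairs: int = 10**6,
    seed: int = 0,
    weighting: str = "unweighted",
) -> tuple[dict, float]:
    """Mean pairwise Euclidean distance within each class on the embedding.

    Intended for [-1, 1]-rescaled coordinates, where the value is
    comparable across runs.  Classes with fewer than 2 cells are
    reported as NaN and excluded from the overall mean across classes,
    which averages classes equally (``unweighted``, so small classes are
    not swamped) or by cell count (``cell_weighted``).  Beyond
    ``max_pairs`` unordered pairs per class the mean is estimated from a
    seeded random pair subsample.
    """
    if weighting not in ("unweighted", "cell_weighted"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    coords = e.coords if isinstance(e, Embedding) else np.asarray(e, float)
    classes = np.asarray(classes)
    if len(classes) != coords.shape[0]:
        raise ValueError("one class label per cell required")
    rng = np.random.default_rng(seed)
    per_class: dict = {}
    for t in np.unique(classes):
        pts = coords[classes == t]
        m = pts.shape[0]
        if m < 2:
            per_class[t] = float("nan")
            continue
        n_pairs = m * (m - 1) // 2
        if n_pairs <= max_pairs:
            per_class[t] = float(pdist(pts).mean())
        else:
            i = rng.integers(0, m, size=max_pairs)
            j = rng.integers(0, m - 1, size=max_pairs)
            j = np.where(j >= i, j + 1, j)
            per_class[t] = float(
                np.linalg.norm(pts[i] - pts[j], axis=1).mean()
            )
    sizes = {t: int((classes == t).sum()) for t in per_class}
    valid = [t for t, v in per_class.items() if not np.isnan(v)]
    if not valid:
        return per_class, float("nan")
    if weighting == "cell_weighted":
        w = np.array([sizes[t] for t in valid], dtype=float)
        overall = float(np.average([per_class[t] for t in valid], weights=w))
    else:
        overall = float(np.mean([per_class[t] for t in valid]))
    return per_class, overall


def annotation_accuracy(
    assigned, truth, mapping: dict | None = None
) -> tuple[float, pd.Series]:
    """Percentage of cells whose cluster-derived type matches the truth.

    ``mapping`` optionally collapses fine-grained truth labels to the
    annotation vocabulary (e.g. grouping related subtypes) before
    comparison; labels it leaves unmapped raise an error.  Returns the
    overall accuracy in percent and the per-type recall.
    """
    assigned = np.asarray([str(x) for x in np.asarray(assigned)], dtype=object)
    truth = np.asarray([str(x) for x in np.asarray(truth)], dtype=object)
    if assigned.shape != truth.shape:
        raise ValueError("assigned and truth must have equal length")
    if mapping is not None:
        mapping = {str(k): str(v) for k, v in mapping.items()}
        unmapped = sorted(set(truth) - set(mapping))
        if unmapped:
            raise ValueError(f"truth labels missing from mapping: {unmapped}")
        truth = np.array([mapping[x] for x in truth], dtype=object)
    correct = assigned == truth
    acc = 100.0 * correct.mean()
    recall = (
        pd.Series(correct, index=pd.Index(truth, name="cell_type"))
        .groupby(level=0)
        .mean()
        .rename("recall")
    )
    return float(acc), recall
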