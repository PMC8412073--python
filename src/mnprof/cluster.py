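"""Average-linkage hierarchical clustering of cells and classifiers.

Agglomerative clustering with Euclidean distance and average (UPGMA)
linkage, the combination used throughout the analysis — for cells on scaled
measurements or disease profiles, and for classifiers on probability,
severity or contribution vectors. UPGMA on a metric distance is monotone,
so merge heights are non-decreasing and cutting below the (k-1) highest
merges yields exactly k clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Merge table in scipy linkage format plus leaf bookkeeping.

    ``merges`` rows are (node_a, node_b, height, size); leaves are 0..n-1,
    internal node i is row i-n.
    """

    merges: np.ndarray  # (n-1, 4)
    leaf_order: np.ndarray
    labels: list[str]
    metric: str = "euclidean"
    linkage: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def hclust_average(x: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """UPGMA dendrogram of the rows of *x* under Euclidean distance."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in clustering input")
    if labels is None:
        labels = [str(i) for i in range(x.shape[0])]
    if len(labels) != x.shape[0]:
        raise ValueError("labels not aligned with rows")
    dist = pdist(x, metric="euclidean")
    # internal sanity: pdist of finite data is symmetric with zero diagonal
    sq = squareform(dist)
    assert np.allclose(sq, sq.T) and np.allclose(np.diag(sq), 0.0)
    Z = hierarchy.linkage(dist, method="average")
    return Dendrogram(
        merges=Z,
        leaf_order=hierarchy.leaves_list(Z),
        labels=list(labels),
    )


def cut_k(d: Dendrogram, k: int) -> np.ndarray:
    """Flat cluster labels from removing the k-1 highest merges.

    Labels are renumbered 0..k-1 by first occurrence, so the output is
    stable across platforms. Note that with duplicate points (zero-height
    merges) fewer than k clusters may be returnable.
    """
    n = d.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.fcluster(d.merges, t=k, criterion="maxclust")
    # renumber by first occurrence
    seen: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def cluster_composition(
    labels: np.ndarray, cells: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and per-cluster condition fractions.

    Returns (counts, fractions): cluster x condition contingency table and
    the same table row-normalized (fractions sum to 1 per cluster).
    """
    labels = np.asarray(labels)
    if len(labels) != len(cells):
        raise ValueError("labels not aligned with annotations")
    counts = pd.crosstab(
        pd.Series(labels, name="cluster"),
        pd.Series(np.asarray(cells["condition"]), name="condition"),
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return counts, fractions


def to_newick(d: Dendrogram) -> str:
    """Newick string of the dendrogram (ultrametric: branch lengths are
    half-height differences between parent and child merges)."""
    n = d.n_leaves
    heights = np.r_[np.zeros(n), d.merges[:, 2]]

    def node(i: int) -> str:
        if i < n:
            return d.labels[i]
        a, b = int(d.merges[i - n, 0]), int(d.merges[i - n, 1])
        h = heights[i] / 2.0
        la = h - heights[a] / 2.0
        lb = h - heights[b] / 2.0
        return f"({node(a)}:{la:.6g},{node(b)}:{lb:.6g})"

    return node(2 * n - 2) + ";"
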