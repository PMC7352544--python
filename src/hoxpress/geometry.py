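"""Cohort geometry: Euclidean tumor/healthy separation and clustering order.

The separation statistic asks whether tumor samples sit farther from the
healthy cloud than healthy samples sit from each other, in the Euclidean
space of the selected genes' log2 expression.  Each healthy sample
contributes its mean distance to the other healthy samples (the intra
vector); each tumor sample contributes its mean distance to all healthy
samples (the inter vector); the two vectors are compared by the Wilcoxon
rank-sum test.

Average-linkage (UPGMA) hierarchical clustering with the Euclidean metric
supplies the leaf orders used to lay out expression heatmaps; rendering
itself is left to any plotting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist, squareform

from .diffexpr import wilcoxon_rank_sum
from .io import CohortPair

__all__ = ["SeparationResult", "Dendrogram", "separation", "average_linkage"]


@dataclass(frozen=True)
class SeparationResult:
    intra_healthy: np.ndarray  # per healthy sample: mean distance to other healthy
    inter: np.ndarray  # per tumor sample: mean distance to healthy samples
    statistic: float
    p: float


def separation(cohort: CohortPair, genes: Iterable[str] | None = None) -> SeparationResult:
    """Intra-healthy vs tumor-to-healthy Euclidean distance comparison."""
    pair = cohort.subset_genes(list(genes)) if genes is not None else cohort
    healthy = pair.healthy.data.to_numpy().T  # samples x genes
    tumor = pair.tumor.data.to_numpy().T
    n_h, n_t = healthy.shape[0], tumor.shape[0]
    if n_h < 2 or n_t < 1:
        raise ValueError(f"need >= 2 healthy and >= 1 tumor samples, got {n_h}/{n_t}")
    d_hh = squareform(pdist(healthy, metric="euclidean"))
    intra = d_hh.sum(axis=1) / (n_h - 1)
    inter = cdist(tumor, healthy, metric="euclidean").mean(axis=1)
    statistic, p = wilcoxon_rank_sum(inter, intra)
    return SeparationResult(intra_healthy=intra, inter=inter, statistic=statistic, p=p)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge list plus the induced leaf order.

    ``merges`` rows are (node_i, node_j, height, size): leaves are numbered
    0..n-1 in input order and internal nodes n, n+1, ... in merge order
    (scipy linkage convention).  Average linkage with the Euclidean metric is
    monotone, so heights are nondecreasing.
    """

    labels: tuple[str, ...]
    merges: np.ndarray
    leaf_order: tuple[str, ...]

    def to_newick(self) -> str:
        n = len(self.labels)
        if n == 1:
            return f"{self.labels[0]};"

        def render(node: int, parent_height: float) -> str:
            if node < n:
                return f"{self.labels[node]}:{parent_height:.6g}"
            i, j, h, _ = self.merges[node - n]
            length = parent_height - h
            return f"({render(int(i), h)},{render(int(j), h)}):{length:.6g}"

        root_h = float(self.merges[-1, 2])
        i, j, _, _ = self.merges[-1]
        return f"({render(int(i), root_h)},{render(int(j), root_h)});"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["node_i", "node_j", "height", "size"]
        )


def average_linkage(
    matrix: pd.DataFrame, axis: Literal["rows", "columns"] = "rows"
) -> Dendrogram:
    """UPGMA clustering of matrix rows or columns (Euclidean metric).

    Deterministic for a given input order; distance ties are resolved by the
    underlying nearest-neighbor chain, which prefers earlier indices.
    """
    data = matrix if axis == "rows" else matrix.T
    labels = tuple(str(x) for x in data.index)
    points = data.to_numpy(dtype=float)
    if len(labels) < 1:
        raise ValueError("nothing to cluster")
    if len(labels) == 1:
        return Dendrogram(labels, np.empty((0, 4)), labels)
    Z = hierarchy.linkage(points, method="average", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return Dendrogram(labels, Z, tuple(labels[i] for i in order))
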