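"""Unsupervised subtype discovery by hierarchical clustering.

Tumors are clustered on their expression profiles over the most variable
genes. The default metric is correlation distance (1 - Pearson r between
sample profiles) with Ward linkage, and the tree is cut into K groups
(default K = 6). Ward's criterion is the default because single-sample
outliers under average/complete linkage can surface as singleton clusters
at the K cut, which starves the downstream one-vs-rest contrasts; average
and complete linkage remain available. Correlation distance is computed on
the matrix as given — median-center genes first (io.median_center_genes)
when absolute baselines should not drive sample similarity, as the
end-to-end pipeline does. Metric, linkage and the variable-gene filter are
all exposed.

Cluster labels are renumbered 1..K by decreasing cluster size, ties broken
by the lexicographically smallest sample ID contained, so results are
reproducible across runs and sample orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .matrix import ExpressionMatrix

DISTANCES = ("correlation", "euclidean")
LINKAGES = ("average", "complete", "ward")


@dataclass
class ClusteringResult:
    labels: np.ndarray  # subtype index 1..k per sample, matrix order
    k: int
    linkage_tree: np.ndarray  # scipy linkage matrix (merge history + heights)
    selected_genes: list[str]


def select_variable_genes(matrix: ExpressionMatrix, n_top: int) -> list[str]:
    """The ``n_top`` genes with largest sample SD; ties broken by gene ID."""
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > matrix.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {matrix.n_genes} genes")
    sd = matrix.values.std(axis=1, ddof=1) if matrix.n_samples > 1 else np.zeros(matrix.n_genes)
    order = sorted(range(matrix.n_genes), key=lambda i: (-sd[i], matrix.gene_ids[i]))
    return [matrix.gene_ids[i] for i in order[:n_top]]


def _sample_distances(
    matrix: ExpressionMatrix, genes: list[str], distance: str
) -> np.ndarray:
    sub = matrix.subset_genes(genes)
    profiles = sub.values.T  # samples x genes
    if distance == "correlation":
        if (profiles.std(axis=1) == 0).any():
            bad = [matrix.sample_ids[j] for j in np.where(profiles.std(axis=1) == 0)[0]]
            raise ValueError(
                f"zero-variance sample profile under correlation distance: {bad[:5]}"
            )
        return pdist(profiles, metric="correlation")
    if distance == "euclidean":
        return pdist(profiles, metric="euclidean")
    raise ValueError(f"distance must be one of {DISTANCES}")


def _renumber(raw_labels: np.ndarray, sample_ids: list[str]) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size, ties by smallest sample ID."""
    clusters = {}
    for c in np.unique(raw_labels):
        members = [sample_ids[j] for j in np.where(raw_labels == c)[0]]
        clusters[c] = (-len(members), min(members))
    ordered = sorted(clusters, key=lambda c: clusters[c])
    mapping = {c: i + 1 for i, c in enumerate(ordered)}
    return np.array([mapping[c] for c in raw_labels])


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    k: int = 6,
    distance: str = "correlation",
    linkage: str = "ward",
) -> ClusteringResult:
    """Cluster samples on ``genes`` and cut the tree into ``k`` groups."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.n_samples:
        raise ValueError(f"k={k} exceeds {matrix.n_samples} samples")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if genes is None:
        genes = list(matrix.gene_ids)
    dist = _sample_distances(matrix, genes, distance)
    tree = hierarchy.linkage(dist, method=linkage)
    raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    return ClusteringResult(
        labels=_renumber(raw, matrix.sample_ids),
        k=k,
        linkage_tree=tree,
        selected_genes=list(genes),
    )


def evaluate_k(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    k_range: range | list[int] = range(2, 9),
    distance: str = "correlation",
    linkage: str = "ward",
) -> pd.DataFrame:
    """Mean silhouette width for each k, on the clustering's own distance.

    Provided as a diagnostic; the pipeline never auto-selects K silently.
    """
    if genes is None:
        genes = list(matrix.gene_ids)
    ks = sorted(k_range)
    if ks and (ks[0] < 2 or ks[-1] > matrix.n_samples - 1):
        raise ValueError("k_range must lie within [2, n_samples - 1]")
    dist = _sample_distances(matrix, genes, distance)
    square = squareform(dist)
    tree = hierarchy.linkage(dist, method=linkage)
    rows = []
    for k in ks:
        labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            sil = float("nan")
        else:
            sil = float(silhouette_score(square, labels, metric="precomputed"))
        rows.append({"k": k, "silhouette": sil})
    return pd.DataFrame(rows).sort_values("k", ignore_index=True)
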