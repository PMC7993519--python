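"""Within-sample clustering of CDR3 k-mer vectors.

Clonotypes are grouped by complete-linkage agglomerative clustering on
Euclidean distances between their k-mer vectors; the dendrogram is cut
adaptively per branch (:mod:`repdab.treecut`).  Cluster centroids are the
*unweighted* arithmetic mean of member k-mer rows — clone sizes are ignored
so a centroid reflects only subsequence composition, not sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import ClonotypeKey
from .kmers import KmerMatrix
from .treecut import cut_tree_adaptive


@dataclass
class ClusterAssignment:
    """Flat cluster labels over one sample's clonotypes plus centroids."""

    sample_id: str
    labels: dict[ClonotypeKey, int]
    centroids: dict[int, np.ndarray] = field(repr=False)
    members: dict[int, list[ClonotypeKey]] = field(repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    @property
    def sizes(self) -> dict[int, int]:
        return {c: len(m) for c, m in self.members.items()}


def compute_centroids(
    matrix: KmerMatrix, labels: np.ndarray
) -> dict[int, np.ndarray]:
    """Unweighted mean k-mer vector per cluster label."""
    if len(labels) != len(matrix.keys):
        raise ValueError("labels must cover every row of the matrix")
    centroids: dict[int, np.ndarray] = {}
    for lab in np.unique(labels):
        mask = labels == lab
        if not mask.any():
            raise ValueError(f"cluster {lab} is empty")
        centroids[int(lab)] = matrix.X[mask].mean(axis=0)
    return centroids


def cluster_within_sample(
    matrix: KmerMatrix,
    min_cluster_size: int = 5,
    deep_split: int = 3,
    linkage_method: str = "complete",
) -> ClusterAssignment:
    """Cluster one sample's k-mer matrix.

    Complete linkage is the default for its cluster stability at fine
    granularity; ``average`` and ``ward`` are accepted for comparison.
    """
    n = len(matrix)
    if n < 2:
        raise ValueError("need at least 2 clonotypes to cluster")
    if linkage_method not in {"complete", "average", "ward"}:
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    dists = pdist(matrix.X, metric="euclidean")
    Z = linkage(dists, method=linkage_method)
    labels = cut_tree_adaptive(Z, min_cluster_size=min_cluster_size, deep_split=deep_split)
    centroids = compute_centroids(matrix, labels)
    members: dict[int, list[ClonotypeKey]] = {int(c): [] for c in centroids}
    for key, lab in zip(matrix.keys, labels):
        members[int(lab)].append(key)
    return ClusterAssignment(
        sample_id=matrix.sample_id,
        labels={k: int(l) for k, l in zip(matrix.keys, labels)},
        centroids=centroids,
        members=members,
    )
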