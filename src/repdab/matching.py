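"""Cross-sample matching of CDR3 clusters into sub-repertoires.

Cluster centroids from all samples are pooled and clustered again, either
by k-means with the number of centroid clusters chosen by the optimal-k
(oK) score, or by the same adaptive dendrogram cut used within samples.
Each centroid cluster is one *sub-repertoire*: a row of the cluster-match
table mapping sample ids to their matched within-sample cluster(s).  If a
sub-repertoire contains several clusters of one sample, those are merged
back in the sample and the centroid recomputed (single pass).

The oK score for a candidate k is ``(nS + avS) / 2`` where, over the k
centroid clusters, ``nS`` is the fraction of clusters whose mean silhouette
exceeds the average cluster silhouette, and ``avS`` is that average
silhouette rescaled from [-1, 1] to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .cluster import ClusterAssignment
from .treecut import cut_tree_adaptive

logger = logging.getLogger(__name__)


def ok_score(cluster_silhouettes: np.ndarray) -> tuple[float, float, float]:
    """(nS, avS, oK) from per-cluster silhouette values.

    nS counts clusters *strictly* above the average, so a perfectly uniform
    silhouette profile gives nS = 0.
    """
    s = np.asarray(cluster_silhouettes, dtype=float)
    if s.size == 0:
        raise ValueError("no clusters")
    avg = s.mean()
    nS = float((s > avg).mean())
    avS = float((avg + 1.0) / 2.0)
    return nS, avS, (nS + avS) / 2.0


@dataclass
class KSelectionResult:
    k: int
    oK: float
    nS: float
    avS: float
    per_k: pd.DataFrame = field(repr=False)
    labels: np.ndarray = field(repr=False, default=None)


def _cluster_silhouettes(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean silhouette per cluster; singleton clusters score 0."""
    sam = silhouette_samples(X, labels)
    return np.array([sam[labels == lab].mean() for lab in np.unique(labels)])


def select_k(
    centroids: np.ndarray,
    k_min: int,
    k_max: int,
    seed: int = 0,
    n_init: int = 10,
) -> KSelectionResult:
    """Run k-means over ``[k_min, k_max]`` and return the k maximising oK.

    Ties break toward smaller k (coarser matching keeps sub-repertoires
    better populated across samples).
    """
    n = centroids.shape[0]
    k_min = max(2, k_min)
    k_max = min(k_max, n - 1)
    if k_min > k_max:
        raise ValueError(f"empty k range after clipping: [{k_min}, {k_max}]")
    rows = []
    best = None
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(centroids)
        nS, avS, oK = ok_score(_cluster_silhouettes(centroids, labels))
        rows.append({"k": k, "nS": nS, "avS": avS, "oK": oK})
        if best is None or oK > best.oK:  # strict: ties keep the smaller k
            best = KSelectionResult(k=k, oK=oK, nS=nS, avS=avS, per_k=None, labels=labels)
    best.per_k = pd.DataFrame(rows)
    return best


@dataclass
class SubRepertoire:
    """One row of the cluster-match table: sample id -> matched cluster ids."""

    id: int
    members: dict[str, set[int]]

    @property
    def n_samples_represented(self) -> int:
        return sum(1 for v in self.members.values() if v)

    def clonotypes(self, assignments: dict[str, ClusterAssignment]) -> dict[str, list]:
        """Per-sample clonotype keys belonging to this sub-repertoire."""
        out = {}
        for sid, clusters in self.members.items():
            keys = []
            for c in clusters:
                keys.extend(assignments[sid].members[c])
            out[sid] = keys
        return out


def pool_centroids(
    assignments: list[ClusterAssignment],
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Stack all samples' centroids; returns (matrix, [(sample_id, cluster_id)])."""
    tags, rows = [], []
    for a in assignments:
        for cid in sorted(a.centroids):
            tags.append((a.sample_id, cid))
            rows.append(a.centroids[cid])
    return np.vstack(rows), tags


def match_clusters(
    assignments: list[ClusterAssignment],
    method: str = "km",
    seed: int = 0,
    k_range: tuple[int, int] | None = None,
    n_init: int = 10,
    min_cluster_size: int = 2,
    deep_split: int = 3,
) -> tuple[list[SubRepertoire], KSelectionResult | None]:
    """Group pooled centroids into sub-repertoires.

    ``method="km"`` selects k by the oK score over a range defaulting to
    [min, max] of the per-sample cluster counts; ``method="hc"`` reuses the
    adaptive dendrogram cut on the centroid dendrogram.
    """
    if len(assignments) < 2:
        raise ValueError("cluster matching needs at least two samples")
    X, tags = pool_centroids(assignments)
    ksel = None
    if method == "km":
        if k_range is None:
            counts = [a.n_clusters for a in assignments]
            k_range = (min(counts), max(counts))
        ksel = select_k(X, k_range[0], k_range[1], seed=seed, n_init=n_init)
        labels = ksel.labels
    elif method == "hc":
        Z = linkage(pdist(X), method="complete")
        labels = cut_tree_adaptive(Z, min_cluster_size=min_cluster_size, deep_split=deep_split)
    else:
        raise ValueError(f"unknown matching method {method!r}")

    subreps: dict[int, SubRepertoire] = {}
    for (sid, cid), lab in zip(tags, labels):
        sr = subreps.setdefault(int(lab), SubRepertoire(id=int(lab), members={}))
        sr.members.setdefault(sid, set()).add(cid)
    return [subreps[i] for i in sorted(subreps)], ksel


def merge_same_sample(
    subreps: list[SubRepertoire],
    assignments: list[ClusterAssignment],
) -> tuple[list[SubRepertoire], dict[str, ClusterAssignment]]:
    """Merge multiple same-sample clusters matched into one sub-repertoire.

    The merged cluster keeps the smallest member cluster id; its centroid is
    recomputed as the unweighted mean over the union of member rows (i.e.
    the size-weighted mean of the member centroids).  One pass, no
    re-matching.
    """
    amap = {a.sample_id: a for a in assignments}
    out_subreps: list[SubRepertoire] = []
    for sr in subreps:
        new_members: dict[str, set[int]] = {}
        for sid, clusters in sr.members.items():
            if len(clusters) <= 1:
                new_members[sid] = set(clusters)
                continue
            a = amap[sid]
            target = min(clusters)
            union_keys: list = []
            total = np.zeros_like(a.centroids[target])
            size = 0
            for c in sorted(clusters):
                union_keys.extend(a.members[c])
                total = total + a.centroids[c] * len(a.members[c])
                size += len(a.members[c])
                if c != target:
                    del a.members[c]
                    del a.centroids[c]
            a.members[target] = union_keys
            a.centroids[target] = total / size
            for k in union_keys:
                a.labels[k] = target
            new_members[sid] = {target}
        out_subreps.append(SubRepertoire(id=sr.id, members=new_members))
    return out_subreps, amap


def match_table(subreps: list[SubRepertoire], sample_ids: list[str]) -> pd.DataFrame:
    """Cluster-match table: rows = sub-repertoires, columns = samples,
    cells = merged cluster id or NA."""
    data = {}
    for sid in sample_ids:
        data[sid] = [
            ",".join(map(str, sorted(sr.members[sid]))) if sid in sr.members and sr.members[sid] else pd.NA
            for sr in subreps
        ]
    return pd.DataFrame(data, index=[sr.id for sr in subreps])
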