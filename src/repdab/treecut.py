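"""Adaptive, per-branch cutting of a hierarchical-clustering dendrogram.

A single fixed cut height handles poorly the mixture of tight, motif-driven
CDR3 clusters and diffuse background that repertoire k-mer spaces produce:
tight clusters close low in the tree while the background keeps merging
almost up to the root, so no one height separates both.  This cut walks the
dendrogram bottom-up, replaying each merge and deciding per branch:

* undersized branches (< ``min_cluster_size`` leaves) are always absorbed
  into their sibling;
* two grown branches are kept apart when the join height exceeds the
  lower branch's mean internal merge height by more than a fraction
  (``deep_split``-controlled) of the total dendrogram height — an
  absolute *gap*, evidence of genuine cluster structure; otherwise they
  merge and the diffuse background keeps coalescing.

The gap is measured from the *mean* internal merge height (not the branch
diameter, which under complete linkage creeps up to the join height even
for tight clusters) and compared on the scale of the whole tree, so that
smoothly growing branches — including ones with near-duplicate cores —
are never fragmented by locally small steps.  Once two branches are kept
apart, later joins never fuse them; undersized siblings arriving later
are absorbed into the largest sub-cluster.  A sample of identical vectors
therefore yields one cluster, while tight sequence families are peeled
off at any depth of the tree.

``deep_split`` (0-4) sets how small a gap, as a fraction of the tree
height, still separates branches; higher values "zoom in" and produce
more, smaller clusters.
"""

from __future__ import annotations

import numpy as np

#: deep_split level -> minimum relative height gap that keeps branches apart
_GAP_BY_DEEPSPLIT = {0: 0.40, 1: 0.30, 2: 0.20, 3: 0.15, 4: 0.10}


def cut_tree_adaptive(
    Z: np.ndarray,
    min_cluster_size: int = 5,
    deep_split: int = 3,
) -> np.ndarray:
    """Cut a scipy linkage matrix into flat cluster labels.

    Parameters
    ----------
    Z
        Linkage matrix from :func:`scipy.cluster.hierarchy.linkage`.
    min_cluster_size
        Branches with fewer leaves are absorbed into their sibling branch.
    deep_split
        Split aggressiveness, 0 (conservative) to 4 (fine-grained).

    Returns
    -------
    Integer labels of length ``n_leaves``, 0-based, deterministic for a
    fixed input ordering.
    """
    if deep_split not in _GAP_BY_DEEPSPLIT:
        raise ValueError(f"deep_split must be in {sorted(_GAP_BY_DEEPSPLIT)}")
    gap = _GAP_BY_DEEPSPLIT[deep_split]
    n = Z.shape[0] + 1
    if n < 2:
        return np.zeros(n, dtype=int)

    # Per dendrogram node: the list of live clusters it contains.  A node
    # holding one cluster is still mergeable; several clusters mean a gap
    # was found below it and the split is final.
    # Each cluster: leaves, plus the sum/count of its internal merge
    # heights (their mean is the branch's characteristic height).
    clusters: list[list[dict]] = [
        [{"leaves": [i], "hsum": 0.0, "hn": 0}] for i in range(n)
    ]

    def _mean_h(c: dict) -> float:
        return c["hsum"] / c["hn"] if c["hn"] else 0.0

    def _fuse(a: dict, b: dict, h: float) -> dict:
        return {
            "leaves": a["leaves"] + b["leaves"],
            "hsum": a["hsum"] + b["hsum"] + h,
            "hn": a["hn"] + b["hn"] + 1,
        }

    root_h = float(Z[-1, 2])
    for i in range(n - 1):
        left, right = int(Z[i, 0]), int(Z[i, 1])
        h = float(Z[i, 2])
        a, b = clusters[left], clusters[right]
        if len(a) == 1 and len(b) == 1:
            ca, cb = a[0], b[0]
            small = min(len(ca["leaves"]), len(cb["leaves"])) < min_cluster_size
            commensurate = h - min(_mean_h(ca), _mean_h(cb)) <= gap * root_h
            merged = [_fuse(ca, cb, h)] if small or commensurate else [ca, cb]
        else:
            # at least one side already split; absorb an undersized live
            # sibling into the largest sub-cluster, otherwise keep all
            live = a + b
            undersized = [
                c
                for side in (a, b)
                if len(side) == 1
                for c in side
                if len(c["leaves"]) < min_cluster_size
            ]
            if undersized:
                c = undersized[0]
                rest = [x for x in live if x is not c]
                host = max(rest, key=lambda x: len(x["leaves"]))
                rest[rest.index(host)] = _fuse(host, c, h)
                merged = rest
            else:
                merged = live
        clusters.append(merged)

    labels = np.empty(n, dtype=int)
    for lab, c in enumerate(clusters[-1]):
        labels[c["leaves"]] = lab
    return labels
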