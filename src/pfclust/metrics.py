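"""Internal and external clustering validation.

Internal validation drives threshold selection: the mean Silhouette width
(dissimilarity = 1 - similarity; every singleton contributes exactly -1)
is the primary score and the Dunn Index breaks ties.  External validation
and run-to-run convergence both use the Rand Index, the fraction of
element pairs on which two partitions agree.
"""

from __future__ import annotations

import warnings

import numpy as np

from .engine import Clustering
from .similarity import SimilarityMatrix

__all__ = [
    "SINGLETON_SILHOUETTE",
    "silhouette_samples",
    "silhouette_mean",
    "dunn_index",
    "rand_index",
]

#: per-point Silhouette score assigned to every singleton
SINGLETON_SILHOUETTE = -1.0


def silhouette_samples(clustering: Clustering, matrix: SimilarityMatrix) -> np.ndarray:
    """Per-point Silhouette widths ``s(i) = (b - a) / max(a, b)``.

    ``a(i)`` is the mean dissimilarity of point *i* to the other members of
    its own cluster; ``b(i)`` is the minimum over all other clusters
    (singletons count as clusters of size one) of the mean dissimilarity to
    that cluster's members.  Singletons receive :data:`SINGLETON_SILHOUETTE`.

    The degenerate clustering consisting of one cluster and no singletons
    has no neighbouring cluster; every point is scored 0 (neutral) and a
    warning is issued.
    """
    if clustering.n != matrix.n:
        raise ValueError("clustering and matrix cover different element counts")
    n = clustering.n
    scores = np.empty(n)
    groups = list(clustering.clusters) + [
        np.array([s]) for s in clustering.singletons
    ]
    if len(groups) == 1:
        warnings.warn(
            "single-cluster clustering: Silhouette undefined, scoring all "
            "points 0",
            stacklevel=2,
        )
        scores.fill(0.0)
        return scores
    D = 1.0 - matrix.values
    # M[i, g]: mean dissimilarity of point i to all members of group g
    M = np.column_stack([D[:, g].mean(axis=1) for g in groups])
    n_multi = len(clustering.clusters)
    for g, members in enumerate(groups):
        if g >= n_multi:  # singleton group
            scores[members[0]] = SINGLETON_SILHOUETTE
            continue
        size = members.size
        # within-group mean over *other* members: remove the zero self-term
        a = M[members, g] * size / (size - 1)
        others = np.delete(M[members], g, axis=1)
        b = others.min(axis=1)
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore"):
            s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
        scores[members] = s
    return scores


def silhouette_mean(clustering: Clustering, matrix: SimilarityMatrix) -> float:
    """Mean Silhouette width over all n points (singletons scored -1)."""
    return float(silhouette_samples(clustering, matrix).mean())


def dunn_index(clustering: Clustering, matrix: SimilarityMatrix) -> float:
    """Dunn Index: min inter-centroid distance over max cluster size.

    The centroid of a cluster is its medoid — the member with maximal mean
    similarity to the other members (ties broken by lowest element index).
    The inter-cluster distance is ``1 - s(centroid_i, centroid_j)``; the
    cluster size is the mean distance of all members (centroid included,
    contributing zero) to the centroid.  Singletons are excluded entirely.

    Returns ``-inf`` when fewer than two multi-member clusters exist
    (undefined; compares as worst in tie-breaking) and ``+inf`` when every
    cluster is internally identical (zero denominator).
    """
    S = matrix.values
    multis = clustering.clusters
    if len(multis) < 2:
        return float("-inf")
    medoids = []
    sizes = []
    for members in multis:
        sub = S[np.ix_(members, members)]
        mean_to_others = (sub.sum(axis=0) - np.diagonal(sub)) / (members.size - 1)
        medoid = members[int(np.argmax(mean_to_others))]  # first max = lowest index
        medoids.append(medoid)
        sizes.append(float(np.mean(1.0 - S[members, medoid])))
    medoids = np.asarray(medoids)
    inter = 1.0 - S[np.ix_(medoids, medoids)]
    min_delta = float(inter[np.triu_indices(len(medoids), k=1)].min())
    max_size = max(sizes)
    if max_size == 0.0:
        return float("inf")
    return min_delta / max_size


def rand_index(c1: Clustering, c2: Clustering) -> float:
    """Rand Index between two partitions of the same elements.

    Over all C(n, 2) unordered pairs, counts agreements — pairs co-clustered
    in both partitions plus pairs separated in both — and divides by the
    total number of pairs.  Singletons count as ordinary clusters.
    """
    if c1.n != c2.n:
        raise ValueError(
            f"partitions cover different element counts ({c1.n} vs {c2.n})"
        )
    n = c1.n
    l1 = c1.labels()
    l2 = c2.labels()
    # contingency table via joint label codes
    joint = l1.astype(np.int64) * (l2.max() + 1) + l2
    nij = np.bincount(np.unique(joint, return_inverse=True)[1]).astype(np.int64)
    ni = np.bincount(l1).astype(np.int64)
    mj = np.bincount(l2).astype(np.int64)

    def _pairs(counts: np.ndarray) -> int:
        return int((counts * (counts - 1) // 2).sum())

    total = n * (n - 1) // 2
    a = _pairs(nij)  # co-clustered in both
    same1 = _pairs(ni)
    same2 = _pairs(mj)
    b = total - same1 - same2 + a  # separated in both
    return (a + b) / total
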