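"""Randomized threshold estimation.

The algorithm's clustering criterion is the mean intra-cluster similarity
E[X] of a cluster.  To choose candidate thresholds on E[X] without
enumerating all Bell(n) partitions, the data are partitioned at random
many times (default N = 1000): each randomization draws a cluster count k
uniformly from {1..n}, assigns every element independently and uniformly
to one of the k slots, and records E[X] for every resulting cluster
(singleton clusters have no member pairs and contribute 0).  The pooled
E[X] values form a reference
distribution whose extreme upper tail — the 5% of sampled clusters with
the highest internal coherence — supplies 20 candidate thresholds: ten
fixed percentiles {95.00, 97.50, 99.00, 99.14, 99.29, 99.43, 99.57,
99.71, 99.86, 100.00} plus the second- through eleventh-highest pooled
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "PERCENTILES",
    "SimilarityDistribution",
    "ThresholdSet",
    "mean_intra_cluster_similarity",
    "random_partition",
    "build_similarity_distribution",
    "extract_thresholds",
    "bell_number",
]

#: the ten fixed upper-tail percentiles used for threshold extraction
PERCENTILES = (95.00, 97.50, 99.00, 99.14, 99.29, 99.43, 99.57, 99.71, 99.86, 100.00)

#: number of top-ranked pooled values used as additional thresholds (ranks 2..11)
TOP_RANKS = range(2, 12)


@dataclass(frozen=True)
class SimilarityDistribution:
    """Pooled per-cluster mean intra-cluster similarities from randomization.

    One value per sampled cluster: E[X] for clusters of two or more
    members, 0 for singleton clusters (zero pairs).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ThresholdSet:
    """Exactly 20 candidate thresholds, sorted descending, with provenance.

    ``provenance[i]`` tags ``thresholds[i]`` as either ``"p<percentile>"``
    or ``"rank<r>"``.  Duplicate values are permitted.
    """

    thresholds: tuple
    provenance: tuple

    def __post_init__(self) -> None:
        if len(self.thresholds) != 20 or len(self.provenance) != 20:
            raise ValueError("a ThresholdSet holds exactly 20 values")

    def unique_values(self) -> np.ndarray:
        """Distinct threshold values, descending."""
        return np.unique(np.asarray(self.thresholds))[::-1]


def mean_intra_cluster_similarity(members, matrix: SimilarityMatrix) -> float:
    """Mean pairwise similarity E[X] among a cluster's members.

    The arithmetic mean of s(i, j) over all C(m, 2) unordered distinct
    pairs; self-similarities are excluded.  Undefined (raises) for fewer
    than two members.
    """
    idx = np.asarray(list(members), dtype=int)
    m = idx.size
    if m < 2:
        raise ValueError(
            "mean intra-cluster similarity is undefined for clusters of "
            f"size {m}; filter singletons before calling"
        )
    sub = matrix.values[np.ix_(idx, idx)]
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def random_partition(n: int, rng: np.random.Generator) -> list:
    """Draw one random partition of ``n`` elements.

    A cluster count k is drawn uniformly from {1..n}; each element is then
    assigned independently and uniformly to one of the k slots.  Slots that
    end up empty are dropped.  Returns a list of index arrays.
    """
    if n < 2:
        raise ValueError("random_partition requires n >= 2")
    k = int(rng.integers(1, n + 1))
    assignment = rng.integers(0, k, size=n)
    order = np.argsort(assignment, kind="stable")
    sorted_assign = assignment[order]
    starts = np.flatnonzero(np.r_[True, sorted_assign[1:] != sorted_assign[:-1]])
    return list(np.split(order, starts[1:]))


def _pooled_ex_values(S: np.ndarray, diag: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """E[X] of every cluster in one random partition (vectorized).

    Sorts elements by slot label and uses segmented reductions to obtain
    each cluster's within-block similarity sum in O(n^2).  Every cluster of
    the partition contributes one value: clusters with at least two members
    contribute their mean pairwise similarity; singleton clusters have no
    pairs and contribute 0.  Pooling the singleton zeros is essential — they
    anchor the lower bulk of the distribution so that its upper percentiles
    fall in the transition region between mixed and coherent clusters.
    """
    n = S.shape[0]
    k = int(rng.integers(1, n + 1))
    assignment = rng.integers(0, k, size=n)
    order = np.argsort(assignment, kind="stable")
    sorted_assign = assignment[order]
    starts = np.flatnonzero(np.r_[True, sorted_assign[1:] != sorted_assign[:-1]])
    sizes = np.diff(np.r_[starts, n])
    # row-reduce then column-reduce the block-sorted matrix; the diagonal of
    # the result is each cluster's total within-block sum (diag included)
    rows = np.add.reduceat(S[order], starts, axis=0)
    block = np.add.reduceat(rows[:, order], starts, axis=1)
    intra = np.diagonal(block) - np.add.reduceat(diag[order], starts)
    sz = sizes.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(sizes >= 2, intra / np.maximum(sz * (sz - 1.0), 1.0), 0.0)
    return ex


def build_similarity_distribution(
    matrix: SimilarityMatrix,
    n_randomizations: int = 1000,
    rng: np.random.Generator | None = None,
) -> SimilarityDistribution:
    """Pool one E[X] value per cluster across N random partitions.

    Singleton clusters contribute 0 (no pairs); all larger clusters
    contribute their mean pairwise similarity.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    rng = np.random.default_rng(rng)
    S = matrix.values
    diag = np.diagonal(S).copy()
    chunks = [
        _pooled_ex_values(S, diag, rng) for _ in range(n_randomizations)
    ]
    values = np.concatenate(chunks) if chunks else np.empty(0)
    if values.size == 0:
        raise ValueError(
            "randomization produced no clusters of size >= 2; "
            "cannot build a similarity distribution"
        )
    return SimilarityDistribution(values)


def extract_thresholds(dist: SimilarityDistribution) -> ThresholdSet:
    """Extract the 20 candidate thresholds from the distribution's tail.

    Ten nearest-rank percentiles (so each threshold is an actually observed
    E[X] value) plus the values of ranks 2..11 when sorted descending.
    """
    values = np.sort(dist.values)  # ascending
    m = values.size
    if m < 11:
        raise ValueError(
            f"only {m} pooled E[X] values; need at least 11 — "
            "increase the number of randomizations"
        )
    out = []
    for p in PERCENTILES:
        # nearest-rank (inverse ECDF) percentile on the sorted sample
        rank = max(1, math.ceil(p / 100.0 * m))
        out.append((float(values[rank - 1]), f"p{p:.2f}"))
    desc = values[::-1]
    for r in TOP_RANKS:
        out.append((float(desc[r - 1]), f"rank{r}"))
    out.sort(key=lambda tv: -tv[0])
    thresholds, provenance = zip(*out)
    return ThresholdSet(thresholds, provenance)


def bell_number(n: int) -> int:
    """Number of set partitions of ``n`` elements, exactly.

    Computed with the Bell triangle in arbitrary-precision integer
    arithmetic; this count motivates random sampling over exhaustive
    enumeration of clusterings.
    """
    if n < 0:
        raise ValueError("bell_number is undefined for negative n")
    row = [1]
    for _ in range(n):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[0]
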