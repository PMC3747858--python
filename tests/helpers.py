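"""Brute-force oracles and small builders shared across the test suite.

Every oracle here is deliberately written as directly as possible —
explicit loops over element pairs, exhaustive enumeration of partitions —
so it stays independent of the vectorized implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from pfclust import Clustering, SimilarityMatrix


def matrix_from_dense(values) -> SimilarityMatrix:
    return SimilarityMatrix(np.asarray(values, dtype=float))


def two_block_matrix(n1: int = 5, n2: int = 5, within: float = 0.9, between: float = 0.1) -> SimilarityMatrix:
    """Block-constant similarity matrix with two perfectly coherent blocks."""
    n = n1 + n2
    S = np.full((n, n), between)
    S[:n1, :n1] = within
    S[n1:, n1:] = within
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S)


def random_similarity_matrix(n: int, rng: np.random.Generator) -> SimilarityMatrix:
    """Random symmetric matrix with off-diagonal values in [-1, 1]."""
    A = rng.uniform(-1.0, 1.0, size=(n, n))
    S = (A + A.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S)


def clustering_from_sets(sets, n: int) -> Clustering:
    clusters = [np.array(sorted(s)) for s in sets if len(s) >= 2]
    singles = sorted(x for s in sets if len(s) == 1 for x in s)
    return Clustering(tuple(clusters), np.array(singles, dtype=int), n)


def all_partitions(items):
    """Exhaustively enumerate all set partitions of ``items`` (recursive)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in all_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield [[first]] + partial


def brute_rand_index(c1: Clustering, c2: Clustering) -> float:
    """Rand Index by explicit enumeration of all element pairs."""
    l1, l2 = c1.labels(), c2.labels()
    n = c1.n
    agree = total = 0
    for i, j in itertools.combinations(range(n), 2):
        same1 = l1[i] == l1[j]
        same2 = l2[i] == l2[j]
        agree += same1 == same2
        total += 1
    return agree / total


def brute_silhouette_mean(clustering: Clustering, matrix: SimilarityMatrix) -> float:
    """Mean Silhouette width by explicit per-point loops.

    Mirrors the definition: a(i) over own-cluster co-members, b(i) the
    minimum mean dissimilarity to any other cluster (singletons included
    as neighbours), singletons scored -1, single-cluster degenerate 0.
    """
    D = 1.0 - matrix.values
    groups = [list(c) for c in clustering.clusters] + [[int(s)] for s in clustering.singletons]
    if len(groups) == 1:
        return 0.0
    scores = []
    for g in groups:
        for i in g:
            if len(g) == 1:
                scores.append(-1.0)
                continue
            a = float(np.mean([D[i, j] for j in g if j != i]))
            b = min(
                float(np.mean([D[i, j] for j in other]))
                for other in groups
                if other is not g
            )
            if max(a, b) == 0:
                scores.append(0.0)
            else:
                scores.append((b - a) / max(a, b))
    return float(np.mean(scores))
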