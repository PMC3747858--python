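"""Threshold-guided clustering of a similarity matrix.

Given a candidate threshold T on the mean intra-cluster similarity E[X],
clusters are grown agglomeratively: the most similar unclustered pair
seeds a cluster (only if their similarity exceeds T), and the cluster
absorbs, one at a time, the unclustered element with the highest average
similarity to the current members, as long as that average reaches P*T
(default P = 0.85) and the grown cluster keeps E[X] > T.  Elements left
over become singletons.  A single refinement pass then re-homes every
point whose average similarity to its own cluster falls below T.

A full run repeats this over all 20 candidate thresholds and keeps the
clustering with the best mean Silhouette width (Dunn Index, then larger
threshold, as tie-breaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .randomization import (
    ThresholdSet,
    build_similarity_distribution,
    extract_thresholds,
)
from .similarity import SimilarityMatrix

__all__ = [
    "Clustering",
    "ThresholdCandidate",
    "RunResult",
    "cluster_at_threshold",
    "refine_clustering",
    "single_run",
]

DEFAULT_P = 0.85


@dataclass(frozen=True)
class Clustering:
    """A partition of ``n`` element indices.

    ``clusters`` holds the multi-member clusters (each an ascending index
    array of size >= 2); ``singletons`` the elements alone in their own
    cluster.  Together they cover every element exactly once.
    """

    clusters: tuple
    singletons: np.ndarray
    n: int

    def __post_init__(self) -> None:
        clusters = tuple(
            np.asarray(sorted(c), dtype=np.intp) for c in self.clusters
        )
        singles = np.asarray(sorted(self.singletons), dtype=np.intp)
        seen = np.concatenate([*clusters, singles]) if clusters or singles.size else singles
        if seen.size != self.n or np.unique(seen).size != self.n or (
            seen.size and (seen.min() < 0 or seen.max() >= self.n)
        ):
            raise ValueError("clusters and singletons must partition range(n)")
        for c in clusters:
            if c.size < 2:
                raise ValueError("multi-member clusters must have >= 2 members")
        object.__setattr__(self, "clusters", clusters)
        object.__setattr__(self, "singletons", singles)

    @classmethod
    def from_labels(cls, labels) -> "Clustering":
        """Build a Clustering from a per-element label array."""
        labels = np.asarray(labels)
        n = labels.size
        clusters, singletons = [], []
        for lab in pd_unique(labels):
            members = np.flatnonzero(labels == lab)
            (clusters if members.size >= 2 else singletons).append(members)
        singles = (
            np.concatenate(singletons) if singletons else np.empty(0, dtype=np.intp)
        )
        return cls(tuple(clusters), singles, n)

    def labels(self) -> np.ndarray:
        """Per-element integer cluster ids (singletons get unique ids)."""
        out = np.empty(self.n, dtype=np.intp)
        for cid, members in enumerate(self.clusters):
            out[members] = cid
        base = len(self.clusters)
        for off, s in enumerate(self.singletons):
            out[s] = base + off
        return out

    @property
    def n_clusters(self) -> int:
        """Total cluster count, inclusive of singletons."""
        return len(self.clusters) + self.singletons.size

    @property
    def n_multi(self) -> int:
        return len(self.clusters)


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in first-appearance order."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


@dataclass(frozen=True)
class ThresholdCandidate:
    """One scored candidate clustering from a run."""

    threshold: float
    silhouette: float
    dunn: float


@dataclass(frozen=True)
class RunResult:
    """Outcome of one complete threshold-selection run."""

    threshold: float
    clustering: Clustering
    silhouette: float
    dunn: float
    candidates: tuple = field(default=(), repr=False)
    warning: str | None = None


def cluster_at_threshold(
    matrix: SimilarityMatrix, T: float, P: float = DEFAULT_P
) -> Clustering:
    """Agglomerate the matrix at threshold ``T`` with admission gate ``P*T``.

    Clusters are seeded by the most similar unclustered pair (similarity
    strictly above T required) and grown greedily; the joining element must
    have average similarity to the members of at least ``P*T`` and must
    leave the cluster's E[X] strictly above T.  Ties anywhere resolve to
    the lowest element index.  Every multi-member cluster of the output
    satisfies E[X] > T.
    """
    if not 0.0 < P <= 1.0:
        raise ValueError("P must be in (0, 1]")
    S = matrix.values
    n = S.shape[0]
    masked = S.copy()
    np.fill_diagonal(masked, -np.inf)
    unclustered = np.ones(n, dtype=bool)
    clusters = []
    while int(unclustered.sum()) >= 2:
        idx = np.flatnonzero(unclustered)
        sub = masked[np.ix_(idx, idx)]
        flat = int(np.argmax(sub))  # row-major first max -> lowest indices
        i, j = divmod(flat, idx.size)
        if not sub[i, j] > T:
            break
        a, b = int(idx[i]), int(idx[j])
        members = [a, b]
        unclustered[a] = unclustered[b] = False
        sim_sum = S[:, a] + S[:, b]  # running sum of similarity to members
        pair_sum = float(S[a, b])  # running sum over member pairs
        m = 2
        while True:
            rem = np.flatnonzero(unclustered)
            if rem.size == 0:
                break
            cand = int(rem[np.argmax(sim_sum[rem])])
            avg = sim_sum[cand] / m
            grown_pairs = pair_sum + sim_sum[cand]
            grown_ex = grown_pairs / ((m + 1) * m / 2)
            if avg >= P * T and grown_ex > T:
                members.append(cand)
                unclustered[cand] = False
                sim_sum = sim_sum + S[:, cand]
                pair_sum = grown_pairs
                m += 1
            else:
                break
        clusters.append(np.array(sorted(members), dtype=np.intp))
    return Clustering(tuple(clusters), np.flatnonzero(unclustered), n)


def refine_clustering(
    clustering: Clustering, matrix: SimilarityMatrix, T: float
) -> Clustering:
    """Single refinement pass re-homing points that sit below T.

    Members of multi-member clusters are visited once in ascending element
    index.  A point whose average similarity to the other members of its
    own cluster is below T is reassigned to the multi-member cluster with
    the maximal average similarity — even if that maximum is itself below
    T.  Moves take effect immediately, so later points see updated
    memberships.  A cluster reduced to one member demotes that member to a
    singleton; singletons themselves are never moved.
    """
    S = matrix.values
    members_of = [list(c) for c in clustering.clusters]
    alive = [True] * len(members_of)
    owner = {}
    for cid, c in enumerate(members_of):
        for p in c:
            owner[p] = cid
    singletons = list(clustering.singletons)
    to_visit = sorted(owner)

    for p in to_visit:
        cid = owner.get(p)
        if cid is None:  # demoted to singleton by an earlier move
            continue
        own = members_of[cid]
        own_avg = (S[p, own].sum() - S[p, p]) / (len(own) - 1)
        if own_avg >= T:
            continue
        best_cid, best_avg = cid, own_avg
        for qid, group in enumerate(members_of):
            if not alive[qid] or qid == cid:
                continue
            avg = S[p, group].mean()
            if avg > best_avg:
                best_cid, best_avg = qid, avg
        if best_cid == cid:
            continue
        own.remove(p)
        members_of[best_cid].append(p)
        owner[p] = best_cid
        if len(own) == 1:  # demote the stranded member
            last = own.pop()
            alive[cid] = False
            del owner[last]
            singletons.append(last)

    clusters = tuple(
        np.array(sorted(c), dtype=np.intp)
        for keep, c in zip(alive, members_of)
        if keep and c
    )
    return Clustering(clusters, np.array(sorted(singletons), dtype=np.intp), clustering.n)


def _score_key(sil: float, dunn: float, T: float) -> tuple:
    return (sil, dunn, T)


def single_run(
    matrix: SimilarityMatrix,
    n_randomizations: int = 1000,
    P: float = DEFAULT_P,
    rng: np.random.Generator | None = None,
    thresholds=None,
) -> RunResult:
    """One complete threshold-selection run.

    Builds the randomized E[X] distribution (unless ``thresholds`` — a
    ThresholdSet or a plain sequence of values — is supplied, which skips
    randomization entirely), clusters and refines at each candidate
    threshold, scores every candidate clustering by mean Silhouette width
    and Dunn Index, and returns the best.  Ties on Silhouette fall to the
    larger Dunn Index, then to the larger threshold.
    """
    from .metrics import dunn_index, silhouette_mean  # deferred: metrics uses Clustering

    if thresholds is None:
        rng = np.random.default_rng(rng)
        dist = build_similarity_distribution(matrix, n_randomizations, rng)
        thresholds = extract_thresholds(dist)
    values = (
        thresholds.thresholds
        if isinstance(thresholds, ThresholdSet)
        else tuple(float(t) for t in thresholds)
    )

    candidates = []
    cache: dict[float, tuple] = {}
    best = None
    for T in values:
        if T not in cache:
            clustering = refine_clustering(
                cluster_at_threshold(matrix, T, P), matrix, T
            )
            cache[T] = (clustering, silhouette_mean(clustering, matrix), dunn_index(clustering, matrix))
        clustering, sil, dunn = cache[T]
        candidates.append(ThresholdCandidate(float(T), sil, dunn))
        key = _score_key(sil, dunn, T)
        if best is None or key > best[0]:
            best = (key, float(T), clustering, sil, dunn)

    _, T_best, clustering, sil, dunn = best
    warning = None
    if clustering.n_multi == 0:
        warning = (
            "every candidate threshold produced an all-singleton clustering; "
            "the data show no cluster structure above the sampled thresholds"
        )
        warnings.warn(warning, stacklevel=2)
    return RunResult(T_best, clustering, sil, dunn, tuple(candidates), warning)
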