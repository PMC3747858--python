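"""Threshold-guided agglomeration, refinement, and run-level selection."""

import numpy as np
import pytest

from helpers import (
    brute_silhouette_mean,
    clustering_from_sets,
    matrix_from_dense,
    random_similarity_matrix,
    two_block_matrix,
)
from pfclust import (
    Clustering,
    cluster_at_threshold,
    mean_intra_cluster_similarity,
    refine_clustering,
    single_run,
)


class TestClustering:
    def test_partition_invariant_enforced(self):
        with pytest.raises(ValueError, match="partition"):
            Clustering((np.array([0, 1]),), np.array([1, 2]), 4)  # 1 twice, 3 missing

    def test_undersized_cluster_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            Clustering((np.array([0]),), np.array([1]), 2)

    def test_labels_round_trip(self):
        c = clustering_from_sets([{0, 2, 5}, {1, 4}, {3}, {6}], 7)
        back = Clustering.from_labels(c.labels())
        assert back.labels().tolist() == c.labels().tolist()
        assert back.n_clusters == 4 and back.n_multi == 2


class TestClusterAtThreshold:
    def test_pair_above_threshold_forms_cluster(self):
        M = matrix_from_dense([[1.0, 0.95], [0.95, 1.0]])
        c = cluster_at_threshold(M, T=0.9)
        assert c.n_multi == 1 and c.singletons.size == 0

    def test_all_singletons_when_no_pair_exceeds_threshold(self):
        S = np.full((6, 6), 0.2)
        np.fill_diagonal(S, 1.0)
        c = cluster_at_threshold(matrix_from_dense(S), T=0.5)
        assert c.n_multi == 0 and c.singletons.size == 6

    def test_two_block_matrix_recovers_blocks(self, two_block):
        c = cluster_at_threshold(two_block, T=0.8)
        got = {frozenset(map(int, cl)) for cl in c.clusters}
        assert got == {frozenset(range(5)), frozenset(range(5, 10))}
        assert c.singletons.size == 0

    def test_every_multimember_cluster_exceeds_threshold(self, rng):
        """Stage 1A postcondition: E[X] > T for every output cluster."""
        for trial in range(25):
            M = random_similarity_matrix(12, rng)
            T = float(rng.uniform(-0.5, 0.9))
            c = cluster_at_threshold(M, T)
            for members in c.clusters:
                assert mean_intra_cluster_similarity(members, M) > T

    def test_deterministic(self, rng):
        M = random_similarity_matrix(15, rng)
        a = cluster_at_threshold(M, 0.3)
        b = cluster_at_threshold(M, 0.3)
        assert a.labels().tolist() == b.labels().tolist()

    def test_monotone_clustered_mass_under_threshold(self):
        M = two_block_matrix(6, 6, within=0.85, between=0.2)
        placed = [
            sum(c.size for c in cluster_at_threshold(M, T).clusters)
            for T in np.linspace(0.0, 1.0, 21)
        ]
        assert all(a >= b for a, b in zip(placed, placed[1:]))


class TestRefineClustering:
    def test_identity_when_all_points_coherent(self, two_block):
        c = cluster_at_threshold(two_block, T=0.8)
        refined = refine_clustering(c, two_block, T=0.8)
        assert refined.labels().tolist() == c.labels().tolist()

    def test_point_moves_to_closer_cluster(self):
        # point 2 sits in {0,1,2} but is far from 0,1 and close to {3,4}
        S = np.array(
            [
                [1.0, 0.9, 0.4, 0.1, 0.1],
                [0.9, 1.0, 0.4, 0.1, 0.1],
                [0.4, 0.4, 1.0, 0.7, 0.7],
                [0.1, 0.1, 0.7, 1.0, 0.9],
                [0.1, 0.1, 0.7, 0.9, 1.0],
            ]
        )
        M = matrix_from_dense(S)
        start = clustering_from_sets([{0, 1, 2}, {3, 4}], 5)
        refined = refine_clustering(start, M, T=0.6)
        labels = refined.labels()
        assert labels[2] == labels[3] == labels[4]
        assert labels[0] == labels[1] != labels[2]

    def test_moves_even_when_best_cluster_below_threshold(self):
        # point 4 below T everywhere, but strictly closest to cluster {2,3}
        S = np.array(
            [
                [1.0, 0.9, 0.1, 0.1, 0.30],
                [0.9, 1.0, 0.1, 0.1, 0.30],
                [0.1, 0.1, 1.0, 0.9, 0.45],
                [0.1, 0.1, 0.9, 1.0, 0.45],
                [0.30, 0.30, 0.45, 0.45, 1.0],
            ]
        )
        M = matrix_from_dense(S)
        start = clustering_from_sets([{0, 1, 4}, {2, 3}], 5)
        refined = refine_clustering(start, M, T=0.8)
        labels = refined.labels()
        assert labels[4] == labels[2]  # moved to {2,3} although 0.45 < T

    def test_drained_cluster_demotes_last_member_to_singleton(self):
        # both members of {3,4} prefer the big cluster; 4 is evaluated after
        # 3 leaves, and whichever remains alone must become a singleton
        S = np.array(
            [
                [1.0, 0.9, 0.9, 0.6, 0.2],
                [0.9, 1.0, 0.9, 0.6, 0.2],
                [0.9, 0.9, 1.0, 0.6, 0.2],
                [0.6, 0.6, 0.6, 1.0, 0.3],
                [0.2, 0.2, 0.2, 0.3, 1.0],
            ]
        )
        M = matrix_from_dense(S)
        start = clustering_from_sets([{0, 1, 2}, {3, 4}], 5)
        refined = refine_clustering(start, M, T=0.8)
        assert refined.n == 5
        labels = refined.labels()
        assert labels[3] == labels[0]
        assert 4 in refined.singletons

    def test_preserves_partition(self, rng):
        for _ in range(20):
            M = random_similarity_matrix(14, rng)
            T = float(rng.uniform(-0.2, 0.8))
            c = cluster_at_threshold(M, T)
            refined = refine_clustering(c, M, T)
            flat = np.sort(
                np.concatenate([*refined.clusters, refined.singletons])
                if refined.clusters
                else refined.singletons
            )
            assert np.array_equal(flat, np.arange(14))


class TestSingleRun:
    def test_constant_matrix_degenerates_with_warning(self):
        S = np.full((8, 8), 0.5)
        np.fill_diagonal(S, 1.0)
        with pytest.warns(UserWarning, match="no cluster structure"):
            result = single_run(
                matrix_from_dense(S), n_randomizations=100, rng=np.random.default_rng(0)
            )
        assert len({c.threshold for c in result.candidates}) == 1
        assert result.clustering.n_multi == 0
        assert result.silhouette == pytest.approx(-1.0)

    def test_two_block_matrix_selects_blocks_from_supplied_thresholds(self, two_block):
        result = single_run(two_block, thresholds=[0.95, 0.8, 0.3])
        got = {frozenset(map(int, c)) for c in result.clustering.clusters}
        assert got == {frozenset(range(5)), frozenset(range(5, 10))}
        assert result.silhouette > 0.8
        assert result.threshold == 0.8

    def test_two_block_matrix_randomized_path_recovers_blocks(self, two_block):
        result = single_run(two_block, n_randomizations=300, rng=np.random.default_rng(1))
        got = {frozenset(map(int, c)) for c in result.clustering.clusters}
        assert got == {frozenset(range(5)), frozenset(range(5, 10))}
        assert result.silhouette > 0.8

    def test_gaussian_groups_recovered_end_to_end(self):
        from pfclust import generate_gaussian_clusters, similarity_from_points
        from pfclust.synthetic import SyntheticSpec

        points = generate_gaussian_clusters(SyntheticSpec(8, 12, seed=3))
        M = similarity_from_points(points)
        result = single_run(M, n_randomizations=400, rng=np.random.default_rng(2))
        gold = Clustering.from_labels(points.labels)
        got = {frozenset(map(int, c)) for c in result.clustering.clusters}
        want = {frozenset(map(int, c)) for c in gold.clusters}
        assert got == want

    def test_deterministic_under_seed(self, rng):
        M = random_similarity_matrix(12, rng)
        r1 = single_run(M, n_randomizations=150, rng=np.random.default_rng(9))
        r2 = single_run(M, n_randomizations=150, rng=np.random.default_rng(9))
        assert r1.threshold == r2.threshold
        assert r1.clustering.labels().tolist() == r2.clustering.labels().tolist()
        assert r1.silhouette == r2.silhouette

    def test_selected_silhouette_is_candidate_maximum_by_brute_force(self, rng):
        """The winner's Silhouette equals the max over all 20 candidates,
        re-scored independently with the brute-force pair-loop oracle."""
        from pfclust.engine import cluster_at_threshold as cat, refine_clustering as ref

        M = random_similarity_matrix(8, rng)
        result = single_run(M, n_randomizations=200, rng=np.random.default_rng(4))
        brute = []
        for cand in result.candidates:
            c = ref(cat(M, cand.threshold), M, cand.threshold)
            brute.append(brute_silhouette_mean(c, M))
        assert result.silhouette == pytest.approx(max(brute))
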