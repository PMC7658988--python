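import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from chromclust import (
    Embedding,
    ValidationError,
    cdf_area,
    consensus_matrix,
    final_partition,
    hclust_partition,
    item_consensus,
)
from chromclust.consensus import relative_area_change


def embedding(scores, prefix="c"):
    scores = np.asarray(scores, dtype=float)
    ids = [f"{prefix}{i}" for i in range(scores.shape[0])]
    return Embedding(scores, np.ones(scores.shape[1]), ids, ["s"] * scores.shape[0])


def two_group_embedding(n_per_group=10, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    a = np.array([5.0, 1.0, -2.0, 3.0]) + jitter * rng.normal(size=(n_per_group, 4))
    b = np.array([-4.0, 2.0, 6.0, -1.0]) + jitter * rng.normal(size=(n_per_group, 4))
    return embedding(np.vstack([a, b]))


class TestHclustPartition:
    def test_duplicated_points_co_assigned(self):
        e = embedding([[1, 2, 3], [1, 2, 3], [9, -1, 4], [9, -1, 4.0]])
        labels = hclust_partition(e, 2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equal_n_gives_singletons(self):
        rng = np.random.default_rng(5)
        e = embedding(rng.random((6, 4)))
        labels = hclust_partition(e, 6)
        assert len(set(labels)) == 6

    def test_matches_reference_agglomerative_oracle(self):
        """Ward cut on 1 - Pearson must agree with a direct scipy pipeline."""
        rng = np.random.default_rng(6)
        scores = np.vstack(
            [rng.normal(0, 0.3, (10, 5)) + [4, 0, 0, 0, 0],
             rng.normal(0, 0.3, (10, 5)) - [4, 0, 0, 0, 0]]
        )
        e = embedding(scores)
        labels = hclust_partition(e, 2)
        dist = 1 - np.corrcoef(scores)
        iu = np.triu_indices(20, k=1)
        ref = fcluster(linkage(dist[iu], method="ward"), 2, criterion="maxclust")
        # same co-membership structure regardless of label names
        ours = labels[:, None] == labels[None, :]
        theirs = ref[:, None] == ref[None, :]
        np.testing.assert_array_equal(ours, theirs)

    def test_constant_score_row_rejected_with_cell_named(self):
        e = embedding([[1, 1, 1], [1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValidationError, match="index 0"):
            hclust_partition(e, 2)

    def test_k_out_of_range(self):
        e = embedding(np.random.default_rng(0).random((4, 3)))
        with pytest.raises(ValidationError):
            hclust_partition(e, 1)
        with pytest.raises(ValidationError):
            hclust_partition(e, 5)


class TestConsensusMatrix:
    def test_two_duplicated_groups_give_block_01_matrix(self):
        e = two_group_embedding(jitter=0.0)
        m = consensus_matrix(e, 2, n_iter=100, frac=0.8, seed=3)
        within = np.zeros((20, 20), dtype=bool)
        within[:10, :10] = within[10:, 10:] = True
        np.testing.assert_allclose(m[within], 1.0)
        np.testing.assert_allclose(m[~within], 0.0)

    def test_reduces_to_single_run_comembership(self):
        e = two_group_embedding(jitter=0.3, seed=9)
        m = consensus_matrix(e, 2, n_iter=1, frac=1.0, seed=0)
        labels = hclust_partition(e, 2)
        expected = (labels[:, None] == labels[None, :]).astype(float)
        np.testing.assert_array_equal(m, expected)

    def test_same_seed_identical(self):
        e = two_group_embedding(jitter=0.5, seed=1)
        m1 = consensus_matrix(e, 2, n_iter=30, seed=42)
        m2 = consensus_matrix(e, 2, n_iter=30, seed=42)
        np.testing.assert_array_equal(m1, m2)

    def test_bounds_symmetry_unit_diagonal(self):
        e = two_group_embedding(jitter=1.5, seed=2)
        m = consensus_matrix(e, 3, n_iter=50, seed=1)
        assert m.min() >= 0 and m.max() <= 1
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_seed_stability_within_sampling_noise(self):
        e = two_group_embedding(jitter=1.2, seed=4)
        m1 = consensus_matrix(e, 2, n_iter=500, seed=1)
        m2 = consensus_matrix(e, 2, n_iter=500, seed=2)
        assert np.abs(m1 - m2).max() <= 0.1

    def test_invalid_params(self):
        e = two_group_embedding()
        with pytest.raises(ValidationError):
            consensus_matrix(e, 2, n_iter=0)
        with pytest.raises(ValidationError):
            consensus_matrix(e, 10, n_iter=5, frac=0.2)  # subsample smaller than k


class TestCdfArea:
    @staticmethod
    def perfect_pairs_matrix():
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = m[2, 3] = m[3, 2] = 1.0
        np.fill_diagonal(m, 1.0)
        return m

    def test_hand_integrated_area(self):
        # upper triangle {1,1,0,0,0,0}: CDF(0) = 4/6, area = 1 * 4/6
        m = self.perfect_pairs_matrix()
        areas, _ = cdf_area({2: m, 3: m})
        assert areas[2] == pytest.approx(2 / 3)

    def test_degenerate_all_ones_has_zero_area(self):
        m = np.ones((4, 4))
        areas, _ = cdf_area({2: m, 3: m})
        assert areas[2] == 0.0

    def test_delta_arithmetic(self):
        deltas = relative_area_change({2: 0.2, 3: 0.5, 4: 0.55})
        assert deltas[2] == pytest.approx(0.2)
        assert deltas[3] == pytest.approx(1.5)
        assert deltas[4] == pytest.approx(0.1)

    def test_zero_previous_area_gives_nan_not_exception(self):
        deltas = relative_area_change({2: 0.0, 3: 0.5})
        assert np.isnan(deltas[3])

    def test_needs_two_ks(self):
        with pytest.raises(ValidationError):
            cdf_area({2: np.ones((3, 3))})


class TestItemConsensus:
    def test_perfect_pairs_score_one(self):
        m = TestCdfArea.perfect_pairs_matrix()
        scores = item_consensus(m, np.array([1, 1, 2, 2]))
        np.testing.assert_allclose(scores, 1.0)

    def test_disconnected_cell_scores_zero(self):
        m = TestCdfArea.perfect_pairs_matrix()
        m[0, 1] = m[1, 0] = 0.0
        scores = item_consensus(m, np.array([1, 1, 2, 2]))
        assert scores[0] == 0.0

    def test_mean_arithmetic(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.8
        m[0, 2] = m[2, 0] = 0.6
        m[1, 2] = m[2, 1] = 0.99
        scores = item_consensus(m, np.array([1, 1, 1]))
        assert scores[0] == pytest.approx(0.7)

    def test_singleton_convention(self):
        m = np.eye(3)
        scores = item_consensus(m, np.array([1, 2, 2]))
        assert scores[0] == 1.0


class TestFinalPartition:
    def test_block_diagonal_recovered(self):
        m = np.zeros((6, 6))
        m[:3, :3] = m[3:, 3:] = 1.0
        assignment = final_partition(m, 2, [f"c{i}" for i in range(6)])
        labels = assignment.labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[5]

    def test_k_one_rejected(self):
        with pytest.raises(ValidationError):
            final_partition(np.eye(4), 1, list("abcd"))
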