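import numpy as np
import pytest

from scsemi import _tape as T
from scsemi.constraints import (align_clusters, build_constraints,
                                class_weights, empty_constraints, label_matrix,
                                make_labeled_mask, pairwise_loss,
                                pairwise_loss_t, pairwise_similarity,
                                sample_triplets, triplet_loss, triplet_loss_t,
                                weighted_ce_loss, weighted_ce_loss_t)


class TestLabeledMask:
    def test_r_zero_empty(self):
        assert len(make_labeled_mask(np.zeros(10, dtype=int), 0.0)) == 0

    def test_r_one_all(self):
        labels = np.array([0, 0, 1, 1, 1])
        np.testing.assert_array_equal(make_labeled_mask(labels, 1.0),
                                      np.arange(5))

    def test_stratified_counts(self):
        labels = np.repeat([0, 1], [900, 100])
        idx = make_labeled_mask(labels, 0.1, seed=0)
        assert len(idx) == 100
        assert (labels[idx] == 0).sum() == 90
        assert (labels[idx] == 1).sum() == 10

    def test_small_class_gets_at_least_one(self):
        labels = np.repeat([0, 1], [99, 1])
        idx = make_labeled_mask(labels, 0.05, seed=0)
        assert (labels[idx] == 1).sum() == 1

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            make_labeled_mask(np.zeros(5, dtype=int), 1.5)


class TestTriplets:
    def test_invariant_holds_for_all_sampled_triples(self):
        labels = np.repeat([0, 1], 2)
        trips = sample_triplets(np.arange(4), labels, n_triplets=500, seed=0)
        assert trips.shape == (500, 3)
        a, p, n = trips.T
        assert np.all(labels[a] == labels[p])
        assert np.all(labels[a] != labels[n])
        assert np.all(a != p)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 labeled classes"):
            sample_triplets(np.arange(4), np.zeros(4, dtype=int), 10, 0)

    def test_seed_reproducible(self):
        labels = np.repeat([0, 1, 2], 5)
        t1 = sample_triplets(np.arange(15), labels, 200, seed=5)
        t2 = sample_triplets(np.arange(15), labels, 200, seed=5)
        np.testing.assert_array_equal(t1, t2)


class TestTripletLoss:
    def test_margin_satisfied_is_zero(self):
        # s(A,P) = 0.9, s(A,N) = 0.5
        Q = np.array([[1.0, 0.0], [0.9, 0.1], [0.5, 0.5]])
        trips = np.array([[0, 1, 2]])
        assert triplet_loss(Q, trips, margin=0.1) == pytest.approx(0.0)

    def test_margin_violated_hinge_value(self):
        # s(A,P) = 0.5, s(A,N) = 0.6 -> hinge 0.2 at margin 0.1
        Q = np.array([[1.0, 0.0], [0.5, 0.5], [0.6, 0.4]])
        trips = np.array([[0, 1, 2]])
        assert triplet_loss(Q, trips, margin=0.1) == pytest.approx(0.2, abs=1e-9)

    def test_identical_anchor_positive_orthogonal_negative(self):
        Q = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        trips = np.array([[0, 1, 2]])
        assert triplet_loss(Q, trips, margin=0.5) == pytest.approx(0.0)

    def test_literal_form_swaps_sign(self):
        Q = np.array([[1.0, 0.0], [0.9, 0.1], [0.5, 0.5]])
        trips = np.array([[0, 1, 2]])
        assert triplet_loss(Q, trips, 0.1, form="literal") == pytest.approx(
            0.5, abs=1e-9)

    def test_empty_triplets_warn_and_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert triplet_loss(np.ones((2, 2)) / 2,
                                np.empty((0, 3), dtype=int)) == 0.0


class TestPairwise:
    def test_identical_rows_similarity_one(self):
        Q = np.tile([0.3, 0.7], (3, 1))
        np.testing.assert_allclose(pairwise_similarity(Q), 1.0)

    def test_orthogonal_one_hot_zero(self):
        S = pairwise_similarity(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert S[0, 1] == pytest.approx(0.0)

    def test_cosine_arithmetic(self):
        S = pairwise_similarity(np.array([[0.8, 0.2], [0.2, 0.8]]))
        assert S[0, 1] == pytest.approx(0.32 / 0.68, abs=1e-9)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pairwise_similarity(np.array([[1.0, 0.0], [0.0, 0.0]]))

    def test_perfect_separation_zero_loss(self):
        Y = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        S = Y.copy()
        assert pairwise_loss(S, Y) == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_similarity_log2(self):
        n = 4
        S = np.full((n, n), 0.5)
        Y = label_matrix(np.array([0, 0, 1, 1]))
        assert pairwise_loss(S, Y) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet(np.ones(3), size=6)
        labels = np.array([0, 1, 0, 2, 1, 0])
        loss = pairwise_loss(pairwise_similarity(Q), label_matrix(labels))
        perm = rng.permutation(6)
        loss_p = pairwise_loss(pairwise_similarity(Q[perm]),
                               label_matrix(labels[perm]))
        assert loss == pytest.approx(loss_p, abs=1e-12)


class TestAlignAndWeights:
    def test_contingency_alignment(self):
        # contingency [[5, 0], [1, 4]] -> identity mapping, agreement 9
        Q = np.zeros((10, 2))
        hard = [0] * 5 + [0] + [1] * 4
        Q[np.arange(10), hard] = 1.0
        labels = np.array([0] * 5 + [1] * 5)
        m = align_clusters(Q, labels)
        assert m.cluster_of(0) == 0 and m.cluster_of(1) == 1

    def test_injective_with_more_clusters_than_classes(self):
        Q = np.zeros((4, 3))
        Q[[0, 1], 0] = 1.0
        Q[[2, 3], 1] = 1.0
        m = align_clusters(Q, np.array([0, 0, 1, 1]))
        assert {m.cluster_of(0), m.cluster_of(1)} == {0, 1}

    def test_balanced_weights_are_one(self):
        np.testing.assert_allclose(class_weights(np.array([0, 0, 1, 1])), 1.0)

    def test_imbalanced_weights(self):
        labels = np.repeat([0, 1], [90, 10])
        np.testing.assert_allclose(class_weights(labels), [100 / 180, 5.0])

    def test_frequency_weighted_mean_is_one(self):
        labels = np.repeat([0, 1, 2], [50, 30, 20])
        w = class_weights(labels)
        counts = np.array([50, 30, 20])
        assert np.average(w, weights=counts) == pytest.approx(1.0)


class TestWeightedCE:
    def _perfect(self):
        labels = np.array([0, 0, 1])
        Q = np.zeros((3, 2))
        Q[[0, 1], 0] = 1.0
        Q[2, 1] = 1.0
        return Q, labels

    def test_perfect_assignment_zero(self):
        Q, labels = self._perfect()
        m = align_clusters(Q, labels)
        w = class_weights(labels)
        assert weighted_ce_loss(Q, labels, m, w) == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_log2(self):
        Q = np.full((2, 2), 0.5)
        labels = np.array([0, 1])
        m = align_clusters(Q, labels)
        w = class_weights(labels)
        assert weighted_ce_loss(Q, labels, m, w) == pytest.approx(np.log(2.0),
                                                                  abs=1e-9)

    def test_minority_upweighting_increases_loss(self):
        # only the single minority cell is misassigned
        labels = np.repeat([0, 1], [4, 1])
        Q = np.zeros((5, 2))
        Q[:4, 0] = 1.0
        Q[4, 0] = 0.9
        Q[4, 1] = 0.1
        m = align_clusters(Q, labels)
        flat = np.ones(2)
        up = np.array([1.0, 3.0])
        assert (weighted_ce_loss(Q, labels, m, up)
                > weighted_ce_loss(Q, labels, m, flat))


class TestBuildAndTape:
    def test_build_constraints_assembles_consistent_set(self):
        labels = np.repeat([0, 1, 2], [50, 30, 20])
        cs = build_constraints(labels, r=0.1, n_triplets=300, seed=1)
        assert cs.n_labeled == 10
        assert cs.Y.shape == (10, 10)
        np.testing.assert_array_equal(np.diag(cs.Y), 1.0)
        np.testing.assert_array_equal(cs.Y, cs.Y.T)
        a, p, n = cs.triplets.T
        assert np.all(labels[a] == labels[p])
        assert np.all(labels[a] != labels[n])

    def test_empty_constraints_unsupervised(self):
        cs = empty_constraints()
        assert cs.n_labeled == 0 and len(cs.triplets) == 0

    def test_tape_losses_match_numpy(self):
        rng = np.random.default_rng(3)
        Q = rng.dirichlet(np.ones(3), size=12)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        trips = sample_triplets(np.arange(12), labels, 40, seed=0)
        a = triplet_loss(Q, trips, 0.1)
        b = triplet_loss_t(T.Tensor(Q[trips[:, 0]]), T.Tensor(Q[trips[:, 1]]),
                           T.Tensor(Q[trips[:, 2]]), 0.1).value
        assert a == pytest.approx(float(b), abs=1e-10)

        Y = label_matrix(labels)
        pw_np = pairwise_loss(pairwise_similarity(Q), Y)
        pw_t = pairwise_loss_t(T.Tensor(Q), Y).value
        assert pw_np == pytest.approx(float(pw_t), abs=1e-8)

        m = align_clusters(Q, labels)
        w = class_weights(labels)
        classes, enc = np.unique(labels, return_inverse=True)
        cols = np.array([m.cluster_of(c) for c in classes])
        ce_np = weighted_ce_loss(Q, labels, m, w)
        ce_t = weighted_ce_loss_t(T.Tensor(Q), enc, cols, w[enc]).value
        assert ce_np == pytest.approx(float(ce_t), abs=1e-10)
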