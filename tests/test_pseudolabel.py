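"""Pseudo-positive augmentation: probability model, entropy, RBF filter."""

import numpy as np
import pytest
import scipy.sparse as sp

from driverplex.pseudolabel import (AugmentConfig, PositiveClusters,
                                    augment_positives, chebyshev_basis,
                                    class_probabilities, entropy_rank,
                                    median_sigma, prediction_entropy,
                                    rbf_cluster_positives, rbf_kernel_matrix,
                                    scaled_laplacian, select_pseudo_positives,
                                    ProbModel)
from driverplex.simulate import SynthConfig, generate, preset


def _ring(n):
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
    return sp.csr_matrix(a)


class TestChebyshev:
    def test_order_zero_is_identity(self, rng):
        X = rng.normal(size=(6, 3))
        basis = chebyshev_basis(scaled_laplacian(_ring(6)), X, 0)
        assert len(basis) == 1
        np.testing.assert_allclose(basis[0], X)

    def test_recurrence_matches_direct_polynomial(self, rng):
        """T_2 X computed by the recurrence equals (2 L^2 - I) X densely."""
        lhat = scaled_laplacian(_ring(8)).toarray()
        X = rng.normal(size=(8, 3))
        basis = chebyshev_basis(sp.csr_matrix(lhat), X, 2)
        np.testing.assert_allclose(basis[2],
                                   (2 * lhat @ lhat - np.eye(8)) @ X,
                                   atol=1e-9)

    def test_scaled_spectrum_in_unit_interval(self):
        lhat = scaled_laplacian(_ring(10)).toarray()
        np.testing.assert_allclose(lhat, lhat.T, atol=1e-12)
        eig = np.linalg.eigvalsh(lhat)
        assert eig.min() >= -1 - 1e-6 and eig.max() <= 1 + 1e-6

    def test_negative_order_rejected(self, rng):
        with pytest.raises(ValueError):
            chebyshev_basis(scaled_laplacian(_ring(4)), rng.normal(size=(4, 2)),
                            -1)


class TestProbModel:
    def test_rows_sum_to_one(self, easy_synth):
        cfg = AugmentConfig(hidden=8, epochs=5)
        P = class_probabilities(easy_synth.graph,
                                easy_synth.visible_positives, cfg, seed=0)
        assert P.shape == (easy_synth.graph.n, 2)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_training_reduces_cross_entropy(self, easy_synth):
        cfg = AugmentConfig(hidden=8, epochs=30)
        model = ProbModel(easy_synth.graph.union_layer(), easy_synth.graph.X,
                          cfg, seed=1)
        pos = easy_synth.visible_positives
        neg = np.setdiff1d(np.arange(easy_synth.graph.n), pos)[:len(pos)]
        idx = np.concatenate([pos, neg])
        y = np.array([1] * len(pos) + [0] * len(neg))
        traj = model.fit(idx, y)
        assert traj[-1] < traj[0]


class TestEntropy:
    def test_closed_values(self):
        P = np.array([[0.5, 0.5], [1.0, 0.0], [0.1, 0.9]])
        H = prediction_entropy(P)
        assert H[0] == pytest.approx(np.log(2), abs=1e-12)
        assert H[1] == pytest.approx(0.0, abs=1e-12)
        assert H[2] == pytest.approx(0.3250829, abs=1e-6)

    def test_bounded_by_log_c(self, rng):
        logits = rng.normal(size=(50, 2))
        P = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        H = prediction_entropy(P)
        assert (H >= 0).all() and (H <= np.log(2) + 1e-12).all()

    def test_rank_filters_sorts_and_truncates(self):
        P = np.array([[0.9, 0.1],   # negative prediction, excluded
                      [0.2, 0.8],   # H ~ 0.500
                      [0.05, 0.95],  # H ~ 0.199
                      [0.4, 0.6],   # H ~ 0.673
                      [0.3, 0.7]])  # labeled, excluded
        cand = entropy_rank(P, unlabeled=np.array([0, 1, 2, 3]),
                            retain_count=2)
        assert [c[0] for c in cand] == [2, 1]
        assert cand[0][1] < cand[1][1]

    def test_empty_candidates_allowed(self):
        P = np.array([[0.9, 0.1], [0.8, 0.2]])
        assert entropy_rank(P, np.array([0, 1]), 5) == []


class TestRBFClustering:
    def test_kernel_is_one_at_zero_distance(self, rng):
        phi = rng.normal(size=(4, 3))
        K = rbf_kernel_matrix(phi, sigma=1.3)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_recovers_two_blobs(self):
        rng = np.random.default_rng(0)
        blob_a = rng.normal(size=(12, 4)) * 0.3
        blob_b = rng.normal(size=(12, 4)) * 0.3 + 5.0
        feats = np.vstack([blob_a, blob_b])
        clusters = rbf_cluster_positives(feats, seed=0)
        labels = clusters.assignments
        # one blob per cluster
        assert len(set(labels[:12])) == 1 and len(set(labels[12:])) == 1
        assert labels[0] != labels[12]
        # centroids near the standardized blob means
        phi = clusters.transform(feats)
        for k in (0, 1):
            members = phi[labels == k]
            np.testing.assert_allclose(clusters.centroids[k],
                                       members.mean(axis=0), atol=1e-9)

    def test_singleton_cluster_centroid_is_member(self):
        feats = np.array([[0.0, 0.0], [0.1, -0.1], [0.2, 0.1], [9.0, 9.0]])
        clusters = rbf_cluster_positives(feats, seed=0)
        sizes = np.bincount(clusters.assignments, minlength=2)
        if 1 in sizes:  # the outlier forms its own cluster
            k = int(np.argmin(sizes))
            member = clusters.transform(feats)[clusters.assignments == k][0]
            np.testing.assert_allclose(clusters.centroids[k], member)

    def test_degenerate_affinity_rejected(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            rbf_cluster_positives(np.ones((5, 3)), seed=0)

    def test_median_sigma_positive(self, rng):
        assert median_sigma(rng.normal(size=(6, 2))) > 0


class TestSelectionRule:
    def _clusters(self):
        return PositiveClusters(
            centroids=np.array([[0.0, 0.0], [4.0, 4.0]]),
            assignments=np.array([0, 0, 1, 1]),
            positive_distances=np.array([0.5, 0.7, 0.4, 0.8]),
            mean_=np.zeros(2), std_=np.ones(2))

    def test_boundary_probability_included(self):
        """p exactly at theta_p passes (the rule is >=)."""
        clusters = self._clusters()
        P = np.zeros((3, 2))
        P[0] = [0.2, 0.8]
        X = np.zeros((3, 2))  # distance 0.0 to centroid 0
        out = select_pseudo_positives([(0, 0.5)], P, clusters, X, theta_p=0.8)
        assert [m.index for m in out.members] == [0]

    def test_boundary_distance_included(self):
        """d exactly at mean + std passes (the rule is <=)."""
        clusters = self._clusters()
        d = clusters.positive_distances
        cutoff = d.mean() + d.std()
        P = np.zeros((2, 2))
        P[1] = [0.05, 0.95]
        # place the candidate exactly at the cutoff distance from centroid 0
        X = np.zeros((2, 2))
        X[1] = [cutoff, 0.0]
        out = select_pseudo_positives([(1, 0.1)], P, clusters, X, theta_p=0.9)
        assert [m.index for m in out.members] == [1]
        X[1] = [cutoff + 1e-9, 0.0]
        out = select_pseudo_positives([(1, 0.1)], P, clusters, X, theta_p=0.9)
        assert len(out) == 0

    def test_no_candidates_yields_empty_set(self):
        out = select_pseudo_positives([], np.zeros((0, 2)), self._clusters(),
                                      np.zeros((0, 2)), 0.8)
        assert len(out) == 0

    def test_distance_clause_only_filters(self, easy_synth):
        """Dropping the RBF distance clause can only enlarge the set."""
        cfg = AugmentConfig(hidden=8, epochs=40)
        pos = easy_synth.visible_positives
        P = class_probabilities(easy_synth.graph, pos, cfg, seed=0)
        unlabeled = np.setdiff1d(np.arange(easy_synth.graph.n), pos)
        cands = entropy_rank(P, unlabeled, retain_count=2 * len(pos))
        clusters = rbf_cluster_positives(easy_synth.graph.X[pos], seed=0)
        with_clause = select_pseudo_positives(cands, P, clusters,
                                              easy_synth.graph.X, 0.8)
        relaxed = PositiveClusters(clusters.centroids, clusters.assignments,
                                   clusters.positive_distances,
                                   clusters.mean_, clusters.std_)
        relaxed.positive_distances = clusters.positive_distances + 1e9
        without_clause = select_pseudo_positives(cands, P, relaxed,
                                                 easy_synth.graph.X, 0.8)
        assert set(m.index for m in with_clause.members) <= \
            set(m.index for m in without_clause.members)


class TestAugmentationRecovery:
    def test_pseudo_labels_enriched_for_hidden_positives(self):
        """Precision of the pseudo-label set against planted ground truth
        beats the unlabeled base rate (averaged over seeds)."""
        precs, bases = [], []
        for seed in range(5):
            data = generate(preset("easy", n=150, n_positives=30, seed=seed))
            cfg = AugmentConfig(hidden=16, epochs=60)
            pseudo = augment_positives(data.graph, data.visible_positives,
                                       cfg, seed=seed)
            truth = set(np.flatnonzero(data.true_labels).tolist())
            n_unl = data.graph.n - len(data.visible_positives)
            bases.append(len(data.hidden_positives) / n_unl)
            if len(pseudo):
                precs.append(np.mean([i in truth for i in pseudo.indices]))
        assert precs, "augmentation never selected anything"
        assert np.mean(precs) > np.mean(bases)
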