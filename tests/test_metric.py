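"""Mahalanobis distance, PSD projection, pair construction, and PGDM fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcra.metric import (MetricMatrix, PairSets, build_pair_sets, mahalanobis,
                         pgdm_fit, pgdm_loss, psd_project)


def naive_pgdm_loss(M, pairs):
    """Double-loop oracle for g(M)."""
    X = pairs.features
    s = 0.0
    for i, j in pairs.S:
        d = X[i] - X[j]
        s += float(d @ M @ d)
    dsum = 0.0
    for i, j in pairs.D:
        d = X[i] - X[j]
        dsum += float(np.sqrt(max(d @ M @ d, 0.0)))
    return s - np.log(dsum)


class TestMahalanobis:
    def test_identity_metric_is_euclidean(self):
        m = MetricMatrix.identity(2)
        assert mahalanobis(m, np.array([1.0, 2.0]), np.array([4.0, 6.0])) == pytest.approx(5.0)

    def test_zero_for_equal_points(self, rng):
        A = rng.normal(size=(3, 3))
        m = psd_project(A @ A.T)
        x = rng.normal(size=3)
        assert mahalanobis(m, x, x) == 0.0

    def test_diagonal_metric(self):
        m = MetricMatrix(np.diag([4.0, 1.0]), np.diag([2.0, 1.0]))
        assert mahalanobis(m, np.array([1.0, 0.0]), np.zeros(2)) == pytest.approx(2.0)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40)
    def test_factorization_identity(self, seed):
        """d_M(x, y) equals ||P (x - y)|| for the stored factor."""
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 6))
        A = rng.normal(size=(d, d))
        m = psd_project(A + A.T)
        x, y = rng.normal(size=d), rng.normal(size=d)
        assert mahalanobis(m, x, y) == pytest.approx(
            np.linalg.norm(m.P.T @ (x - y)), abs=1e-8)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40)
    def test_triangle_inequality_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        m = psd_project(A @ A.T)
        x, y, z = (rng.normal(size=3) for _ in range(3))
        assert mahalanobis(m, x, y) == pytest.approx(mahalanobis(m, y, x))
        assert mahalanobis(m, x, z) <= mahalanobis(m, x, y) + mahalanobis(m, y, z) + 1e-9

    def test_non_psd_metric_rejected(self):
        with pytest.raises(ValueError):
            MetricMatrix(np.diag([1.0, -1.0]), np.eye(2))


class TestPsdProject:
    def test_psd_input_unchanged(self, rng):
        A = rng.normal(size=(4, 4))
        M = A @ A.T
        assert np.allclose(psd_project(M).M, M, atol=1e-10)

    def test_negative_eigenvalue_clipped(self):
        out = psd_project(np.diag([1.0, -1.0]))
        assert np.allclose(out.M, np.diag([1.0, 0.0]), atol=1e-12)

    def test_asymmetric_input_symmetrized_then_clipped(self):
        # [[0,2],[0,0]] -> symmetrize [[0,1],[1,0]] (eigs +-1) -> clip -> 0.5*[[1,1],[1,1]]
        out = psd_project(np.array([[0.0, 2.0], [0.0, 0.0]]))
        assert np.allclose(out.M, 0.5 * np.ones((2, 2)), atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            psd_project(np.array([[np.nan, 0.0], [0.0, 1.0]]))


class TestBuildPairSets:
    def test_exhaustive_enumeration_three_points(self):
        X = np.zeros((3, 2))
        ps = build_pair_sets(X, np.array([0, 0, 1]), max_pairs=10)
        assert ps.S == [(0, 1)]
        assert set(ps.D) == {(0, 2), (1, 2)}

    def test_max_pairs_caps_both_sets(self, rng):
        X = rng.normal(size=(10, 2))
        labels = np.repeat([0, 1], 5)
        ps = build_pair_sets(X, labels, max_pairs=1, seed=0)
        assert len(ps.S) == 1 and len(ps.D) == 1

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 3))
        labels = rng.integers(0, 3, size=50)
        a = build_pair_sets(X, labels, max_pairs=100, seed=42)
        b = build_pair_sets(X, labels, max_pairs=100, seed=42)
        assert a.S == b.S and a.D == b.D

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_pair_sets(np.zeros((4, 2)), np.zeros(4))

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            PairSets(S=[(0, 1)], D=[(0, 1)], features=np.zeros((2, 2)))


class TestPgdmLoss:
    def test_zero_metric_rejected(self):
        ps = PairSets(S=[], D=[(0, 1)], features=np.array([[0.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="log"):
            pgdm_loss(np.zeros((2, 2)), ps)

    def test_direct_substitution(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ps = PairSets(S=[(0, 1)], D=[(0, 2)], features=X)
        # one S pair with difference (1,0): d^2 = 1; one D pair (0,1): log(1) = 0
        assert pgdm_loss(np.eye(2), ps) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        labels = np.array([0, 0, 1, 1, 2])
        ps = build_pair_sets(X, labels, max_pairs=100, seed=0)
        assert pgdm_loss(np.eye(3), ps) == pytest.approx(
            naive_pgdm_loss(np.eye(3), ps), abs=1e-12)


def planted_direction_data(rng, n_per_class=30, sep=3.0, noise=(0.3, 1.5)):
    """Two 2-d classes separated along axis 0 only (small within-class spread
    there); axis 1 is class-free noise with large spread."""
    a = rng.normal(size=(n_per_class, 2)) * noise
    b = rng.normal(size=(n_per_class, 2)) * noise
    b[:, 0] += sep
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], n_per_class)
    return X, labels


def grid_search_diagonal_direction(pairs, n_grid=199):
    """Brute-force direction oracle over diagonal metrics.

    For a fixed direction diag(t, 1-t), the loss at the optimal overall scale
    c is g(c*M) with c* = 1/(2A), A = sum_S d_M^2 (the scale profile of
    g(cM) = cA - log(sqrt(c) K) is exact). Minimizing the profiled loss over
    t gives the oracle's preferred axis weighting free of scale effects.
    """
    best_t, best_score = None, np.inf
    for t in np.linspace(0.005, 0.995, n_grid):
        M = np.diag([t, 1.0 - t])
        A = sum(float((pairs.features[i] - pairs.features[j]) @ M
                      @ (pairs.features[i] - pairs.features[j]))
                for i, j in pairs.S)
        K = sum(np.sqrt(max(float((pairs.features[i] - pairs.features[j]) @ M
                                  @ (pairs.features[i] - pairs.features[j])), 0.0))
                for i, j in pairs.D)
        score = 0.5 * np.log(2 * A) + 0.5 - np.log(K)
        if score < best_score:
            best_t, best_score = t, score
    return best_t, best_score


class TestPgdmFit:
    def test_loss_trace_non_increasing(self, rng):
        X, labels = planted_direction_data(rng)
        pairs = build_pair_sets(X, labels, max_pairs=200, seed=1)
        _, trace = pgdm_fit(pairs, max_iter=100)
        diffs = np.diff(trace)
        assert (diffs <= 1e-12).all()

    def test_max_iter_zero_returns_identity_direction(self, rng):
        X, labels = planted_direction_data(rng)
        pairs = build_pair_sets(X, labels, max_pairs=50, seed=1)
        m, trace = pgdm_fit(pairs, max_iter=0)
        off = m.M - np.diag(np.diag(m.M))
        assert np.allclose(off, 0.0, atol=1e-12)
        assert np.allclose(m.M[0, 0], m.M[1, 1], atol=1e-12)
        assert trace == []

    def test_learned_metric_beats_identity_and_prefers_clean_axis(self, rng):
        """On the planted-direction toy, the fitted M (i) improves g over the
        identity and (ii) shares the diagonal-grid brute-force minimizer's
        axis preference (down-weight the class-free noisy axis 1)."""
        X, labels = planted_direction_data(rng)
        pairs = build_pair_sets(X, labels, max_pairs=400, seed=2)
        m, trace = pgdm_fit(pairs, max_iter=300)
        assert trace[-1] < pgdm_loss(np.eye(2), pairs)
        t_star, _ = grid_search_diagonal_direction(pairs)
        assert t_star > 0.5          # oracle keeps the separating axis
        assert m.M[1, 1] < m.M[0, 0]  # fit de-emphasizes the noise axis too

    def test_symmetric_classes_stay_near_isotropic(self, rng):
        """Whitened data with identically distributed classes: no direction is
        preferred, so the eigenvalue spread of the fitted M stays small."""
        X = rng.normal(size=(800, 2))
        labels = rng.integers(0, 2, size=800)
        pairs = build_pair_sets(X, labels, max_pairs=6000, seed=3)
        m, _ = pgdm_fit(pairs, max_iter=150)
        w = np.linalg.eigvalsh(m.M)
        assert w[1] / max(w[0], 1e-12) <= 1.2

    def test_d_constraint_met(self, rng):
        X, labels = planted_direction_data(rng)
        pairs = build_pair_sets(X, labels, max_pairs=100, seed=4)
        m, _ = pgdm_fit(pairs, max_iter=100)
        dsum = sum(mahalanobis(m, X[i], X[j]) for i, j in pairs.D)
        assert dsum >= 1.0 - 1e-9

    def test_centroid_separation_beats_euclidean(self, rng):
        """After normalizing total within-class spread, the learned-metric
        distance between class centroids exceeds the Euclidean counterpart."""
        X, labels = planted_direction_data(rng)
        pairs = build_pair_sets(X, labels, max_pairs=400, seed=5)
        m, _ = pgdm_fit(pairs, max_iter=300)
        c0, c1 = X[labels == 0].mean(axis=0), X[labels == 1].mean(axis=0)

        def spread(metric):
            return np.mean([mahalanobis(metric, X[i], X[j]) for i, j in pairs.S])

        eye = MetricMatrix.identity(2)
        ratio_learned = mahalanobis(m, c0, c1) / spread(m)
        ratio_euclid = mahalanobis(eye, c0, c1) / spread(eye)
        assert ratio_learned > ratio_euclid
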