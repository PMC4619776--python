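"""Vector quantization: nearest-neighbor oracle, Lloyd descent, LBG growth."""

import itertools

import numpy as np
import pytest

import ark16s as a
from ark16s.clustering import (
    assign_nearest,
    cluster_probabilities,
    lbg_grow,
    lloyd_iterate,
)
from ark16s.errors import ShapeError, TooFewPointsError


def brute_force_2partition(points):
    """Globally optimal 2-cluster distortion by exhaustive enumeration."""
    n = len(points)
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if not mask.any() or mask.all():
            continue
        total = 0.0
        for side in (mask, ~mask):
            sub = points[side]
            total += ((sub - sub.mean(axis=0)) ** 2).sum()
        best = min(best, total / n)
    return best


def two_bump_instance(seed, d=4, sd=0.05, min_sep=0.6):
    """n <= 12 points from two well-separated Gaussian bumps."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 13))
    while True:
        c1, c2 = rng.uniform(0, 1, d), rng.uniform(0, 1, d)
        if np.linalg.norm(c1 - c2) >= min_sep:
            break
    n1 = int(rng.integers(3, n - 2))
    return np.vstack(
        [rng.normal(c1, sd, (n1, d)), rng.normal(c2, sd, (n - n1, d))]
    )


class TestAssignNearest:
    def test_points_at_centroids(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0]])
        np.testing.assert_array_equal(assign_nearest(pts, pts), [0, 1])

    def test_tie_breaks_to_lowest_index(self):
        pts = np.array([[0.5, 0.0]])
        cents = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert assign_nearest(pts, cents)[0] == 0

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.random((200, 7))
        cents = rng.random((5, 7))
        expected = np.array(
            [min(range(5), key=lambda q: ((p - cents[q]) ** 2).sum()) for p in pts]
        )
        np.testing.assert_array_equal(assign_nearest(pts, cents), expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeError):
            assign_nearest(np.zeros((3, 4)), np.zeros((2, 5)))


class TestClusterProbabilities:
    def test_direct_ratio(self):
        np.testing.assert_allclose(
            cluster_probabilities(np.array([0, 0, 0, 1, 1]), 2), [0.6, 0.4]
        )

    def test_single_region(self):
        np.testing.assert_array_equal(cluster_probabilities(np.zeros(9, int), 1), [1.0])

    def test_matches_tally_oracle(self, rng):
        asg = rng.integers(0, 6, size=500)
        P = cluster_probabilities(asg, 6)
        expected = np.array([(asg == q).sum() for q in range(6)]) / 500
        np.testing.assert_array_equal(P, expected)
        assert P.sum() == 1.0


class TestLloydIterate:
    def test_fixed_point(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        cents = np.array([[0.5], [10.5]])
        new, asg, dist = lloyd_iterate(pts, cents)
        np.testing.assert_allclose(new, cents)
        assert dist == pytest.approx(0.25)

    def test_mean_update(self):
        pts = np.array([[0.0], [2.0]])
        new, _, _ = lloyd_iterate(pts, np.array([[5.0]]))
        assert new[0, 0] == pytest.approx(1.0)

    def test_distortion_non_increasing(self, rng):
        pts = rng.random((150, 5))
        cents = rng.random((4, 5))
        prev = np.inf
        for _ in range(20):
            cents, _, dist = lloyd_iterate(pts, cents)
            assert dist <= prev + 1e-12
            prev = dist


class TestLBG:
    def test_single_cluster_is_global_mean(self, rng):
        pts = rng.random((30, 6))
        cl = a.lbg_cluster(pts, 1)
        np.testing.assert_allclose(cl.centroids[0], pts.mean(axis=0))
        np.testing.assert_array_equal(cl.probabilities, [1.0])

    def test_two_separated_masses(self, rng):
        m1 = rng.normal([0, 0, 0], 0.01, (20, 3))
        m2 = rng.normal([5, 5, 5], 0.01, (20, 3))
        cl = a.lbg_cluster(np.vstack([m1, m2]), 2)
        got = {tuple(np.round(c)) for c in cl.centroids}
        assert got == {(0.0, 0.0, 0.0), (5.0, 5.0, 5.0)}
        within = (((m1 - m1.mean(0)) ** 2).sum() + ((m2 - m2.mean(0)) ** 2).sum()) / 40
        assert cl.distortion == pytest.approx(within, rel=1e-9)

    def test_q_equals_n_zero_distortion(self, rng):
        pts = rng.random((6, 3))
        cl = a.lbg_cluster(pts, 6)
        assert cl.Q == 6
        assert cl.distortion == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_instances(self, seed):
        pts = two_bump_instance(seed)
        cl = a.lbg_cluster(pts, 2, seed=seed)
        assert cl.distortion <= brute_force_2partition(pts) * (1 + 1e-9) + 1e-15

    def test_monotone_refinement(self, rng):
        """Converged distortion never increases when Q grows by one."""
        pts = rng.dirichlet(np.ones(8), size=120)
        dists = [cl.distortion for cl in lbg_grow(pts, 8)]
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(dists, dists[1:]))

    def test_recovers_planted_partition(self, rng):
        """Well-separated bumps on the simplex are recovered exactly."""
        from sklearn.metrics import adjusted_rand_score

        centers = np.eye(4) * 0.9 + 0.025
        labels = np.repeat(np.arange(4), 25)
        pts = np.abs(rng.normal(centers[labels], 0.01))
        cl = a.lbg_cluster(pts, 4, seed=0)
        assert adjusted_rand_score(labels, cl.assignments) == 1.0

    def test_agrees_with_sklearn_objective(self, rng):
        """On clusterable data LBG and scikit-learn's k-means (independent
        implementation, 10 restarts) converge to the same objective value."""
        from sklearn.cluster import KMeans

        centers = rng.random((5, 6)) * 3
        labels = rng.integers(0, 5, size=200)
        pts = rng.normal(centers[labels], 0.05)
        cl = a.lbg_cluster(pts, 5)
        km = KMeans(n_clusters=5, n_init=10, random_state=0).fit(pts)
        assert cl.distortion == pytest.approx(km.inertia_ / len(pts), rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(TooFewPointsError):
            a.lbg_cluster(np.zeros((3, 2)), 4)


class TestRandomPartition:
    def test_q1_equals_global_mean_summary(self, rng):
        pts = rng.random((50, 4))
        cl = a.random_partition(pts, 1, seed=3)
        np.testing.assert_allclose(cl.centroids[0], pts.mean(axis=0))

    def test_q_equals_n_singletons(self, rng):
        pts = rng.random((8, 3))  # distinct with probability 1
        cl = a.random_partition(pts, 8, seed=0)
        assert cl.Q == 8
        np.testing.assert_allclose(cl.probabilities, np.full(8, 1 / 8))

    def test_deterministic_per_seed(self, rng):
        pts = rng.random((60, 5))
        c1 = a.random_partition(pts, 7, seed=42)
        c2 = a.random_partition(pts, 7, seed=42)
        assert np.array_equal(c1.assignments, c2.assignments)
        assert np.array_equal(c1.centroids, c2.centroids)


class TestClusteringInvariants:
    @pytest.mark.parametrize("strategy", ["lbg", "random"])
    def test_probabilities_and_centroid_identity(self, strategy, rng):
        """P sums to one, no empty clusters, centroids are subset means, and
        the P-weighted centroid mean equals the global mean."""
        for seed in range(10):
            pts = rng.dirichlet(np.ones(10), size=80)
            Q = int(rng.integers(2, 9))
            if strategy == "lbg":
                cl = a.lbg_cluster(pts, Q, seed=seed)
            else:
                cl = a.random_partition(pts, Q, seed=seed)
            assert cl.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert all(len(cl.members(q)) >= 1 for q in range(cl.Q))
            for q in range(cl.Q):
                np.testing.assert_allclose(
                    cl.centroids[q], pts[cl.members(q)].mean(axis=0), atol=1e-9
                )
            np.testing.assert_allclose(
                cl.probabilities @ cl.centroids, pts.mean(axis=0), atol=1e-9
            )
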