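"""Vector quantization of read feature vectors.

ARK partitions the k-mer feature space into Q Voronoi regions.  Two
strategies are provided:

* **deterministic** — the Linde-Buzo-Gray (LBG) algorithm: start from the
  single global mean, repeatedly split one centroid into a perturbed pair
  and refine with Lloyd iterations (nearest-neighbor assignment under
  squared Euclidean distance, then centroid update) until the distortion
  stops decreasing.  Which centroid to split is a policy choice: by default
  the cluster contributing the most to the total distortion, alternatively
  the most probable (largest) cluster.

* **random** — sample Q distinct data points as representation vectors,
  assign every point once by the nearest-neighbor rule, and recompute
  subset means.  No iterative refinement; this is the cheap strategy for
  very large read sets.

Cluster probabilities P_q are occupancy fractions: the number of feature
vectors in region q over the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyClusterError, ShapeError, TooFewPointsError
from .kmers import FeatureMatrix

logger = logging.getLogger(__name__)

SPLIT_EPS = 1e-3
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100


@dataclass
class Clustering:
    """A partition of N feature vectors into Q nonempty Voronoi regions."""

    Q: int
    centroids: np.ndarray  # (Q, D)
    assignments: np.ndarray  # (N,) ints in [0, Q)
    probabilities: np.ndarray  # (Q,) occupancy fractions, sum to 1
    distortion: float  # mean squared distance of points to their centroids
    seed: int | None = None
    strategy: str = "deterministic"

    def members(self, q: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == q)

    def to_dict(self) -> dict:
        """JSON-serializable record sufficient to reproduce the run."""
        return {
            "Q": int(self.Q),
            "strategy": self.strategy,
            "seed": self.seed,
            "probabilities": self.probabilities.tolist(),
            "centroids": self.centroids.tolist(),
            "assignments": self.assignments.tolist(),
            "distortion": float(self.distortion),
        }


def _as_points(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.rows
    return np.asarray(features, dtype=float)


def _sq_distances(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(N, Q) squared Euclidean distances, clipped at zero for roundoff."""
    # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; the BLAS route matters at
    # N = 10^4+, D = 4^6.
    d2 = (
        (points * points).sum(axis=1)[:, None]
        - 2.0 * points @ centroids.T
        + (centroids * centroids).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def assign_nearest(
    features: FeatureMatrix | np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    """Assign each point to its squared-Euclidean-nearest centroid.

    Ties break toward the lowest centroid index (argmin convention).
    """
    points = _as_points(features)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or points.shape[1] != centroids.shape[1]:
        raise ShapeError(
            f"points have dim {points.shape[1]}, centroids {centroids.shape}"
        )
    # the ||x||^2 term is constant across centroids, so argmin can skip it
    scores = (centroids * centroids).sum(axis=1)[None, :] - 2.0 * points @ centroids.T
    return np.argmin(scores, axis=1)


def cluster_probabilities(assignments: np.ndarray, Q: int) -> np.ndarray:
    """P_q = (number of feature vectors in region q) / N."""
    assignments = np.asarray(assignments, dtype=int)
    if assignments.size and (assignments.min() < 0 or assignments.max() >= Q):
        raise ValueError("assignment outside [0, Q)")
    return np.bincount(assignments, minlength=Q) / assignments.size


def _distortion(points, centroids, assignments) -> float:
    diffs = points - centroids[assignments]
    return float((diffs * diffs).sum() / points.shape[0])


def _cluster_means(
    points: np.ndarray, assignments: np.ndarray, Q: int, fallback: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster means via an indicator matmul (BLAS beats masked loops at
    read-set scale).  Empty clusters keep their ``fallback`` row."""
    n = points.shape[0]
    counts = np.bincount(assignments, minlength=Q).astype(float)
    ind = np.zeros((Q, n))
    ind[assignments, np.arange(n)] = 1.0
    sums = ind @ points
    means = np.array(fallback, dtype=float, copy=True)
    nonempty = counts > 0
    means[nonempty] = sums[nonempty] / counts[nonempty, None]
    return means, counts


def lloyd_iterate(
    features: FeatureMatrix | np.ndarray,
    centroids: np.ndarray,
    x2: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd pass: assign, repair empty clusters, update centroids.

    An empty cluster is re-seeded with the point currently farthest from its
    assigned centroid.  Distortion is reported for the updated codebook and
    is non-increasing relative to the incoming one when no repair occurred.
    """
    points = _as_points(features)
    assignments = assign_nearest(points, centroids)
    Q = centroids.shape[0]
    counts = np.bincount(assignments, minlength=Q)
    while (counts == 0).any():
        empty = int(np.flatnonzero(counts == 0)[0])
        dists = ((points - centroids[assignments]) ** 2).sum(axis=1)
        # never steal from a singleton cluster, or repair could cycle
        movable = counts[assignments] >= 2
        if not movable.any():
            break
        dists = np.where(movable, dists, -np.inf)
        far = int(np.argmax(dists))
        logger.warning("re-seeding empty cluster %d with point %d", empty, far)
        assignments[far] = empty
        counts = np.bincount(assignments, minlength=Q)
    new_centroids, counts_f = _cluster_means(
        points, assignments, Q, np.asarray(centroids, dtype=float)
    )
    # updated centroids are exact subset means, so the within-cluster sum of
    # squares collapses to sum ||x||^2 - sum_q n_q ||c_q||^2
    if x2 is None:
        x2 = float((points * points).sum())
    c2 = (new_centroids * new_centroids).sum(axis=1)
    distortion = max(x2 - float(counts_f @ c2), 0.0) / points.shape[0]
    return new_centroids, assignments, distortion


def _lloyd_converge(
    points: np.ndarray,
    centroids: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, float]:
    prev = np.inf
    x2 = float((points * points).sum())
    assignments = np.zeros(points.shape[0], dtype=int)
    distortion = np.inf
    for _ in range(max_iter):
        centroids, assignments, distortion = lloyd_iterate(points, centroids, x2=x2)
        if prev - distortion <= tol * max(prev, 1e-300):
            break
        prev = distortion
    return centroids, assignments, distortion


def _finalize(points, centroids, assignments, seed, strategy) -> Clustering:
    # drop any cluster that ended empty, renumbering compactly
    Q = centroids.shape[0]
    counts = np.bincount(assignments, minlength=Q)
    keep = np.flatnonzero(counts > 0)
    if keep.size < Q:
        logger.warning("dropping %d empty cluster(s)", Q - keep.size)
        remap = -np.ones(Q, dtype=int)
        remap[keep] = np.arange(keep.size)
        assignments = remap[assignments]
        centroids = centroids[keep]
        Q = keep.size
    # centroids are exact subset means, so the cheap WCSS identity applies
    centroids, counts_f = _cluster_means(points, assignments, Q, centroids)
    x2 = float((points * points).sum())
    c2 = (centroids * centroids).sum(axis=1)
    distortion = max(x2 - float(counts_f @ c2), 0.0) / points.shape[0]
    return Clustering(
        Q=Q,
        centroids=centroids,
        assignments=assignments,
        probabilities=cluster_probabilities(assignments, Q),
        distortion=distortion,
        seed=seed,
        strategy=strategy,
    )


def _split_pair(
    points_q: np.ndarray, c: np.ndarray, eps: float
) -> np.ndarray:
    """Two perturbed copies of centroid ``c`` along the cluster's principal
    direction, offset by eps times the spread along it.

    Splitting along the direction of maximal within-cluster variance makes
    the first Lloyd assignment cut the cluster where it is widest; a
    coordinate-scaling perturbation is the fallback for degenerate
    (zero-variance) clusters.
    """
    X = points_q - c
    # deterministic power iteration for the leading principal direction
    norms = (X * X).sum(axis=1)
    if norms.max() <= 0.0:
        return np.vstack([c * (1.0 + eps), c * (1.0 - eps)])
    v = X[int(np.argmax(norms))]
    v = v / np.linalg.norm(v)
    for _ in range(20):
        w = X.T @ (X @ v)
        nw = np.linalg.norm(w)
        if nw == 0.0:
            break
        v = w / nw
    spread = float(np.sqrt((X @ v) ** 2).mean()) or 1.0
    delta = eps * spread * v
    return np.vstack([c + delta, c - delta])


def _split_rank(points, centroids, assignments, policy: str) -> int:
    """Index of the cluster to split: 'distortion' picks the largest total
    within-cluster squared distance, 'probability' the most populated."""
    Q = centroids.shape[0]
    counts = np.bincount(assignments, minlength=Q)
    if policy == "probability":
        return int(np.argmax(counts))
    # per-cluster WCSS = sum_{x in q} ||x||^2 - n_q ||c_q||^2 (means identity)
    row_sq = (points * points).sum(axis=1)
    contrib = np.bincount(assignments, weights=row_sq, minlength=Q) - counts * (
        centroids * centroids
    ).sum(axis=1)
    return int(np.argmax(contrib))


def lbg_grow(
    features: FeatureMatrix | np.ndarray,
    Q_max: int,
    seed: int | None = None,
    *,
    split_policy: str = "distortion",
    split_eps: float = SPLIT_EPS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
):
    """Yield converged LBG clusterings for Q = 1, 2, ..., Q_max.

    Each level is refined from the previous codebook by splitting the
    highest-ranking cluster, so level Q reuses all work done up to Q-1.
    """
    points = _as_points(features)
    n = points.shape[0]
    if Q_max < 1:
        raise ValueError("Q_max must be >= 1")
    if n < Q_max:
        raise TooFewPointsError(f"{n} points cannot fill {Q_max} clusters")
    centroids = points.mean(axis=0, keepdims=True)
    assignments = np.zeros(n, dtype=int)
    yield _finalize(points, centroids.copy(), assignments.copy(), seed, "deterministic")
    while centroids.shape[0] < Q_max:
        q = _split_rank(points, centroids, assignments, split_policy)
        pair = _split_pair(points[assignments == q], centroids[q], split_eps)
        centroids = np.vstack([np.delete(centroids, q, axis=0), pair])
        centroids, assignments, _ = _lloyd_converge(points, centroids, tol, max_iter)
        result = _finalize(points, centroids.copy(), assignments.copy(), seed,
                           "deterministic")
        # keep growing from the repaired codebook
        centroids, assignments = result.centroids.copy(), result.assignments.copy()
        yield result


def lbg_cluster(
    features: FeatureMatrix | np.ndarray,
    Q_target: int,
    seed: int | None = None,
    *,
    split_policy: str = "distortion",
    split_eps: float = SPLIT_EPS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Clustering:
    """LBG vector quantization growing the codebook from 1 to ``Q_target``.

    Starting from the global mean, the highest-ranking cluster (see
    ``split_policy``) is split into c(1+eps), c(1-eps) and the enlarged
    codebook is refined by Lloyd iterations until the relative distortion
    decrease falls below ``tol`` or ``max_iter`` passes.  Deterministic:
    ``seed`` is only recorded for provenance.
    """
    result = None
    for result in lbg_grow(
        features,
        Q_target,
        seed,
        split_policy=split_policy,
        split_eps=split_eps,
        tol=tol,
        max_iter=max_iter,
    ):
        pass
    assert result is not None
    return result


def random_partition(
    features: FeatureMatrix | np.ndarray, Q: int, seed: int
) -> Clustering:
    """Single-pass partition from Q randomly chosen representation vectors.

    Q distinct data points are sampled without replacement, every point is
    assigned once by the nearest-neighbor rule, and centroids are recomputed
    as subset means.  Representation vectors that attract no points are
    dropped (with a warning) and Q shrinks accordingly.
    """
    points = _as_points(features)
    n = points.shape[0]
    if n < Q:
        raise TooFewPointsError(f"{n} points cannot seed {Q} clusters")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=Q, replace=False)
    reps = points[chosen]
    assignments = assign_nearest(points, reps)
    return _finalize(points, reps.copy(), assignments, seed, "random")
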