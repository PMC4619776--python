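"""The ARK driver: cluster, estimate per cluster, fuse.

The method estimates a community composition p(C_m) from a read set in four
steps: (1) partition the read k-mer feature vectors into Q Voronoi regions,
(2) compute each region's occupancy probability P_q and conditional mean
mu_q, (3) run a base composition estimator on each mu_q to get
p(C_m | x in R_q), (4) fuse the per-cluster estimates as the mixture

    p(C_m) = sum_q P_q * p(C_m | x in R_q).

With Q = 1 this collapses exactly to running the base estimator on the
global sample mean, i.e. the unmodified underlying method.

Two strategies choose Q: the *random* strategy fixes Q up front and
partitions once from random representation vectors (cheap, for very large
read sets); the *deterministic* strategy grows Q by LBG splits from 1
upwards and stops when the fused estimate moves, in scaled variational
distance, by less than a threshold eta between consecutive Q, or when
Q_max is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import clustering as clus
from .errors import AlignmentError, InvalidConfigError, ZeroEstimateError
from .estimators import EstimatorConfig, run_estimator
from .kmers import FeatureMatrix, mean_profile
from .reference import CompositionEstimate, ReferenceMatrix

logger = logging.getLogger(__name__)


@dataclass
class ArkConfig:
    """Driver configuration.

    strategy: 'deterministic' (adaptive LBG) or 'random' (fixed Q).
    Q: cluster count for the random strategy (default 75, the fixed-Q
        operating point used throughout the evaluation).
    eta: stopping threshold in (0, 1] on the scaled variational distance
        between fused estimates at consecutive Q (default 0.01).
    Q_max: cap for the adaptive loop; conventionally a power of two in the
        16-256 range (default 64).
    min_cluster_size: clusters smaller than this are still estimated
        (default 1 = no filtering) but the knob is exposed.
    """

    strategy: str = "deterministic"
    Q: int = 75
    eta: float = 0.01
    Q_max: int = 64
    seed: int = 0
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    min_cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.strategy not in ("deterministic", "random"):
            raise InvalidConfigError(f"unknown strategy {self.strategy!r}")
        if not (0.0 < self.eta <= 1.0):
            raise InvalidConfigError("eta must lie in (0, 1]")
        if self.Q_max < 1 or self.Q < 1:
            raise InvalidConfigError("Q and Q_max must be >= 1")


@dataclass
class ArkResult:
    """Outcome of one ARK run: the fused estimate plus full provenance."""

    estimate: CompositionEstimate
    Q_used: int
    per_cluster_estimates: list[CompositionEstimate]
    P: np.ndarray
    trace: list[float] = field(default_factory=list)  # per-Q scaled-VD deltas
    clustering: clus.Clustering | None = None

    def to_sidecar(self) -> dict:
        return {
            "Q_used": int(self.Q_used),
            "P": self.P.tolist(),
            "trace": self.trace,
            "seed": None if self.clustering is None else self.clustering.seed,
            "strategy": None if self.clustering is None else self.clustering.strategy,
        }


def fuse(
    per_cluster: list[CompositionEstimate], P: np.ndarray
) -> CompositionEstimate:
    """Mixture fusion p(C_m) = sum_q P_q * p(C_m | x in R_q)."""
    P = np.asarray(P, dtype=float)
    if len(per_cluster) != P.size:
        raise AlignmentError("one probability per cluster estimate required")
    taxa = per_cluster[0].taxa
    for est in per_cluster[1:]:
        if est.taxa != taxa:
            raise AlignmentError("per-cluster estimates are over different taxa")
    stacked = np.vstack([est.p for est in per_cluster])
    return CompositionEstimate(list(taxa), P @ stacked)


def _estimate_clusters(
    features: FeatureMatrix,
    ref: ReferenceMatrix,
    clustering: clus.Clustering,
    est_config: EstimatorConfig,
) -> list[CompositionEstimate]:
    """Base estimator on each region's conditional mean mu_q.

    A cluster on which the estimator degenerates to the zero solution
    contributes the uniform distribution (with a warning) so fusion still
    conserves probability mass.
    """
    out: list[CompositionEstimate] = []
    uniform = np.full(ref.n_taxa, 1.0 / ref.n_taxa)
    for q in range(clustering.Q):
        mu_q = mean_profile(features, clustering.members(q))
        try:
            out.append(run_estimator(mu_q, ref, est_config))
        except ZeroEstimateError:
            logger.warning("cluster %d: zero estimate, using uniform", q)
            out.append(CompositionEstimate(list(ref.taxa), uniform.copy()))
    return out


def adaptive_Q_loop(
    features: FeatureMatrix, ref: ReferenceMatrix, config: ArkConfig
) -> ArkResult:
    """Deterministic strategy: grow Q by LBG splits until convergence.

    Runs Q = 1, 2, 3, ... and stops as soon as the scaled variational
    distance sum_m |p(C_m)|_Q - p(C_m)|_{Q-1}| falls below eta, or Q reaches
    Q_max.  Returns the estimate at the stopping Q (the later, more refined
    one); ``trace`` records the delta at each Q >= 2.
    """
    prev_estimate: CompositionEstimate | None = None
    trace: list[float] = []
    result: ArkResult | None = None
    for clustering in clus.lbg_grow(features, config.Q_max, config.seed):
        per_cluster = _estimate_clusters(features, ref, clustering, config.estimator)
        fused = fuse(per_cluster, clustering.probabilities)
        result = ArkResult(
            estimate=fused,
            Q_used=clustering.Q,
            per_cluster_estimates=per_cluster,
            P=clustering.probabilities,
            trace=trace,
            clustering=clustering,
        )
        if prev_estimate is not None:
            delta = float(np.abs(fused.p - prev_estimate.p).sum())
            trace.append(delta)
            if delta < config.eta:
                break
        prev_estimate = fused
    assert result is not None
    return result


def ark_estimate(
    features: FeatureMatrix, ref: ReferenceMatrix, config: ArkConfig | None = None
) -> ArkResult:
    """Run ARK end-to-end on featurized reads against a reference.

    Random strategy: one partition at the configured Q, per-cluster
    estimation, fusion.  Deterministic strategy: the adaptive-Q loop.
    """
    if config is None:
        config = ArkConfig()
    if features.rows.shape[1] != ref.columns.shape[0]:
        raise AlignmentError(
            f"feature dim {features.rows.shape[1]} does not match reference "
            f"dim {ref.columns.shape[0]} (different k?)"
        )
    if config.strategy == "deterministic":
        return adaptive_Q_loop(features, ref, config)
    clustering = clus.random_partition(features, config.Q, config.seed)
    per_cluster = _estimate_clusters(features, ref, clustering, config.estimator)
    fused = fuse(per_cluster, clustering.probabilities)
    return ArkResult(
        estimate=fused,
        Q_used=clustering.Q,
        per_cluster_estimates=per_cluster,
        P=clustering.probabilities,
        trace=[],
        clustering=clustering,
    )
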