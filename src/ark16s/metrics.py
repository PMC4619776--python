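"""Evaluation measures: variational distance, Jensen-Shannon divergence,
and principal coordinates analysis (classical MDS).

Variational distance VD = 0.5 * ||p - q||_1 in [0, 1] is the accuracy
measure for composition estimates (0 = identical, 1 = disjoint supports).
Jensen-Shannon divergence (log base 2, so the maximum is exactly 1) serves
as a between-sample distance; its square root is a metric and feeds the
PCoA ordination of many samples.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import jensenshannon

from .errors import AlignmentError, InvalidDistanceError
from .reference import CompositionEstimate

logger = logging.getLogger(__name__)


def _aligned(p, q) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, CompositionEstimate) and isinstance(q, CompositionEstimate):
        if p.taxa != q.taxa:
            raise AlignmentError("compositions are over different taxa/orders")
        return p.p, q.p
    pv = p.p if isinstance(p, CompositionEstimate) else np.asarray(p, dtype=float)
    qv = q.p if isinstance(q, CompositionEstimate) else np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise AlignmentError(f"shape mismatch {pv.shape} vs {qv.shape}")
    return pv, qv


def variational_distance(p, q) -> float:
    """0.5 * sum_m |p_m - q_m|; symmetric, zero iff p == q."""
    pv, qv = _aligned(p, q)
    return 0.5 * float(np.abs(pv - qv).sum())


def jensen_shannon(p, q) -> float:
    """Jensen-Shannon divergence in bits: 0.5 KL(p||m) + 0.5 KL(q||m),
    m = (p+q)/2, log base 2, with 0 log 0 := 0.  Lies in [0, 1]."""
    pv, qv = _aligned(p, q)
    # scipy returns the JS *distance* sqrt(JSD); square back to the divergence
    d = jensenshannon(pv, qv, base=2)
    if np.isnan(d):  # identical distributions can produce 0/0 upstream
        return 0.0
    return min(float(d) ** 2, 1.0)


def js_distance_matrix(profiles: list[CompositionEstimate]) -> np.ndarray:
    """Symmetric matrix of sqrt(JSD) between all sample pairs."""
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = np.sqrt(jensen_shannon(profiles[i], profiles[j]))
    return D


def pcoa(D: np.ndarray, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical multidimensional scaling of a distance matrix.

    Double-centers -0.5 * D^2, eigendecomposes, and returns the coordinates
    along the top ``dims`` nonnegative eigenpairs together with the fraction
    of (positive) eigenvalue mass each axis explains.  Negative eigenvalues
    (non-Euclidean distances) are dropped with a warning.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise InvalidDistanceError(f"distance matrix must be square, got {D.shape}")
    if not np.allclose(D, D.T, atol=1e-12) or np.abs(np.diag(D)).max() > 1e-12:
        raise InvalidDistanceError("matrix must be symmetric with zero diagonal")
    if dims > max(n - 1, 1):
        raise InvalidDistanceError(f"dims={dims} exceeds n-1={n - 1}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    if (eigvals < -tol).any():
        logger.warning(
            "dropping %d negative eigenvalue(s): distances are non-Euclidean",
            int((eigvals < -tol).sum()),
        )
    pos = np.clip(eigvals, 0.0, None)
    coords = eigvecs[:, :dims] * np.sqrt(pos[:dims])
    total = pos.sum()
    explained = pos[:dims] / total if total > 0 else np.zeros(dims)
    return coords, explained
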