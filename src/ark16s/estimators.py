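"""Per-cluster composition estimators.

Given a mean k-mer profile mu and a reference matrix A, an estimator returns
a probability vector over taxa explaining mu as a nonnegative mixture of
reference columns.  Two estimators ship behind one contract:

* :func:`estimate_nnls` — nonnegative least squares on the design matrix
  augmented with a lambda-weighted sum-to-one row, so the constraint
  sum(x) = 1 is enforced softly but, for large lambda, effectively hard.
* :func:`estimate_nn_omp` — nonnegative greedy pursuit: grow the active
  column set by the largest positive residual correlation, refit by NNLS on
  the active set, stop at a sparsity cap or small residual.

Both normalize the raw column weights to the simplex and then sum weights
per taxon (relevant when split references give a taxon several columns).

Third-party estimators plug in via the same ``(mu, ref, config) ->
CompositionEstimate`` signature; see :data:`ESTIMATORS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .errors import InvalidConfigError, ShapeError, ZeroEstimateError
from .kmers import KmerProfile
from .reference import CompositionEstimate, ReferenceMatrix, aggregate_columns_to_taxa

DEFAULT_LAMBDA = 1e4
DEFAULT_TOL = 1e-6


@dataclass
class EstimatorConfig:
    """Configuration for the pluggable base estimator.

    method: 'nnls_regularized' or 'nn_omp'.
    lam: weight of the sum-to-one row in the NNLS augmentation (> 0).
    max_support: sparsity cap for the greedy pursuit; None means
        min(n_taxa, 100) resolved against the reference at call time.
    tol: residual-norm stopping threshold for the pursuit.
    """

    method: str = "nnls_regularized"
    lam: float = DEFAULT_LAMBDA
    max_support: int | None = None
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        if self.method not in ("nnls_regularized", "nn_omp"):
            raise InvalidConfigError(f"unknown estimator method {self.method!r}")
        if self.lam <= 0:
            raise InvalidConfigError("lambda must be positive")
        if self.max_support is not None and self.max_support < 1:
            raise InvalidConfigError("max_support must be >= 1")


def _check_mu(mu: KmerProfile | np.ndarray, ref: ReferenceMatrix) -> np.ndarray:
    vec = mu.values if isinstance(mu, KmerProfile) else np.asarray(mu, dtype=float)
    if vec.shape != (ref.columns.shape[0],):
        raise ShapeError(
            f"profile dim {vec.shape} vs reference dim {ref.columns.shape[0]}"
        )
    return vec


def estimate_nnls(
    mu: KmerProfile | np.ndarray,
    ref: ReferenceMatrix,
    lam: float = DEFAULT_LAMBDA,
) -> CompositionEstimate:
    """Sum-constrained nonnegative least squares.

    Solves min_{x >= 0} || [A; lam*1^T] x - [mu; lam] ||_2 and aggregates the
    normalized column weights per taxon.  Deterministic.
    """
    vec = _check_mu(mu, ref)
    if lam <= 0:
        raise InvalidConfigError("lambda must be positive")
    A_aug = np.vstack([ref.columns, np.full((1, ref.n_cols), lam)])
    b_aug = np.concatenate([vec, [lam]])
    x, _ = nnls(A_aug, b_aug)
    return aggregate_columns_to_taxa(x, ref)


def estimate_nn_omp(
    mu: KmerProfile | np.ndarray,
    ref: ReferenceMatrix,
    max_support: int | None = None,
    tol: float = DEFAULT_TOL,
) -> CompositionEstimate:
    """Nonnegative orthogonal matching pursuit.

    Iteratively adds the column with the largest positive correlation to the
    current residual, refits the active set by NNLS, and stops when the
    support reaches ``max_support``, the residual norm drops below ``tol``,
    or no column correlates positively with the residual.
    """
    vec = _check_mu(mu, ref)
    A = ref.columns
    n_cols = A.shape[1]
    if max_support is None:
        max_support = min(ref.n_taxa, 100)
    max_support = min(max_support, n_cols)
    if max_support < 1:
        raise InvalidConfigError("max_support must be >= 1")

    col_norms = np.linalg.norm(A, axis=0)
    col_norms[col_norms == 0] = 1.0
    active: list[int] = []
    in_active = np.zeros(n_cols, dtype=bool)
    residual = vec.copy()
    x_active = np.zeros(0)
    while len(active) < max_support and np.linalg.norm(residual) > tol:
        corr = (A.T @ residual) / col_norms
        corr[in_active] = -np.inf
        j = int(np.argmax(corr))
        if corr[j] <= 0:
            if not active:
                raise ZeroEstimateError("no column correlates with the profile")
            break
        active.append(j)
        in_active[j] = True
        x_active, _ = nnls(A[:, active], vec)
        residual = vec - A[:, active] @ x_active
    if not active or x_active.sum() <= 0:
        raise ZeroEstimateError("pursuit produced an all-zero solution")
    weights = np.zeros(n_cols)
    weights[active] = x_active
    return aggregate_columns_to_taxa(weights, ref)


def run_estimator(
    mu: KmerProfile | np.ndarray, ref: ReferenceMatrix, config: EstimatorConfig
) -> CompositionEstimate:
    """Dispatch to the configured estimator."""
    if config.method == "nnls_regularized":
        return estimate_nnls(mu, ref, config.lam)
    return estimate_nn_omp(mu, ref, config.max_support, config.tol)


ESTIMATORS = {
    "nnls": "nnls_regularized",
    "nnls_regularized": "nnls_regularized",
    "omp": "nn_omp",
    "nn_omp": "nn_omp",
}
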