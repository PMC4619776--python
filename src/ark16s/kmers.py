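"""k-mer featurization of nucleotide sequences.

Reads and reference sequences are summarized as vectors of overlapping k-mer
frequencies over the 4^k possible words in lexicographic order (A < C < G < T).
Each read's count vector is normalized to sum to one, so that reads of unequal
length contribute equally to sample means; the sample mean of these profiles
is the feature the downstream composition estimators consume.

Counting is single-strand: no reverse-complement canonicalization is applied,
under the assumption that reads and reference sequences are co-oriented
(standard for amplicon data sequenced from a fixed primer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateReadError, EmptyClusterError, InvalidAlphabetError

logger = logging.getLogger(__name__)

_BASES = "ACGT"

# 256-entry byte -> base code table; -1 marks anything outside ACGT (case-folded).
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class KmerProfile:
    """A normalized k-mer frequency vector of length 4^k.

    Entries are nonnegative and sum to one for any sequence containing at
    least one valid k-mer window.
    """

    values: np.ndarray
    k: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4**self.k,):
            raise InvalidAlphabetError(
                f"profile length {v.shape} does not match 4^{self.k}"
            )
        object.__setattr__(self, "values", v)


@dataclass
class FeatureMatrix:
    """Per-read k-mer profiles stacked as rows, with matching read IDs."""

    rows: np.ndarray  # (N, 4^k)
    read_ids: list[str]
    k: int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.read_ids):
            raise ValueError("rows/read_ids length mismatch")

    @property
    def n_reads(self) -> int:
        return self.rows.shape[0]


def kmer_index(kmer: str) -> int:
    """Lexicographic index of ``kmer`` among all words of its length.

    A=0, C=1, G=2, T=3, most-significant position first, so ``AA...A`` maps
    to 0 and ``TT...T`` to 4^k - 1.
    """
    idx = 0
    for ch in kmer:
        code = _CODE[ord(ch)]
        if code < 0:
            raise InvalidAlphabetError(f"invalid base {ch!r} in k-mer {kmer!r}")
        idx = idx * 4 + int(code)
    return idx


def _window_indices(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Lexicographic index of every length-k window plus a validity mask.

    Built by k shifted accumulations (idx = idx*4 + next code), which keeps
    everything in fast vectorized integer ops.
    """
    n_windows = codes.size - k + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    indices = np.zeros(n_windows, dtype=np.int64)
    valid = np.ones(n_windows, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_windows]
        valid &= c >= 0
        indices = indices * 4 + np.where(c >= 0, c, 0)
    return indices, valid


def count_kmers(sequence: str, k: int) -> np.ndarray:
    """Count overlapping k-mers (step 1, given strand only).

    Windows containing any non-ACGT symbol are skipped.  A sequence shorter
    than ``k`` yields an all-zero vector.  Case-insensitive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = _CODE[np.frombuffer(sequence.encode("latin-1"), dtype=np.uint8)]
    indices, valid = _window_indices(codes, k)
    return np.bincount(indices[valid], minlength=4**k)


def profile(sequence: str, k: int) -> KmerProfile:
    """Normalized k-mer frequency profile of one sequence.

    Raises :class:`DegenerateReadError` when the sequence contains no valid
    k-mer window (shorter than k, or every window hits an ambiguous base).
    """
    counts = count_kmers(sequence, k)
    total = counts.sum()
    if total == 0:
        raise DegenerateReadError(
            f"sequence of length {len(sequence)} has no valid {k}-mer window"
        )
    return KmerProfile(counts / total, k)


def featurize(
    sequences: Iterable[tuple[str, str]],
    k: int,
    *,
    use_counts: bool = False,
) -> FeatureMatrix:
    """Build a :class:`FeatureMatrix` from ``(read_id, sequence)`` pairs.

    Reads with no valid k-mer window are dropped with a logged warning.
    With ``use_counts=True`` rows hold raw counts instead of frequencies, so
    longer reads weigh proportionally more in sample means (the alternative
    reading of "mean vector of k-mer counts"); the default averages per-read
    frequencies.
    """
    pairs = list(sequences)
    if not pairs:
        raise DegenerateReadError("no reads supplied")
    all_ids = [read_id for read_id, _ in pairs]
    # batch all reads into one code array, separated by an invalid sentinel
    # so no window spans two reads, then count all windows in one pass
    n_reads = len(pairs)
    joined = ("\x00" * (k - 1)).join(seq for _, seq in pairs) if k > 1 else "".join(
        seq for _, seq in pairs
    )
    codes = _CODE[np.frombuffer(joined.encode("latin-1"), dtype=np.uint8)]
    dim = 4**k
    rows = np.zeros((n_reads, dim), dtype=float)
    indices, valid_mask = _window_indices(codes, k)
    valid = np.flatnonzero(valid_mask)
    if valid.size:
        # map window start position -> read index via read start offsets
        lengths = np.asarray([len(seq) for _, seq in pairs], dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(lengths + (k - 1))[:-1]])
        read_of = np.searchsorted(starts, valid, side="right") - 1
        flat = np.bincount(read_of * dim + indices[valid], minlength=n_reads * dim)
        rows = flat.reshape(n_reads, dim).astype(float)
    totals = rows.sum(axis=1)
    keep = totals > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d read(s) with no valid %d-mer window", dropped, k)
    if not keep.any():
        raise DegenerateReadError("no read contained a valid k-mer window")
    rows = rows[keep]
    if not use_counts:
        rows /= rows.sum(axis=1, keepdims=True)
    ids = [rid for rid, ok in zip(all_ids, keep) if ok]
    return FeatureMatrix(rows, ids, k)


def mean_profile(
    features: FeatureMatrix, subset: Sequence[int] | np.ndarray | None = None
) -> KmerProfile:
    """Arithmetic mean of the selected rows.

    With ``subset=None`` this is the global sample mean mu; with ``subset``
    equal to the index set of one Voronoi region it is the conditional mean
    mu_q for that region.
    """
    if subset is None:
        rows = features.rows
    else:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise EmptyClusterError("mean_profile of an empty subset")
        rows = features.rows[subset]
    return KmerProfile(rows.mean(axis=0), features.k)
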