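"""Reference database construction.

The composition estimators solve mu ~ A p where the columns of A are k-mer
profiles of reference 16S sequences.  Two modes are supported:

* ``whole``: one column per reference sequence.
* ``split``: sequences longer than ``min_length`` (default 700 bp) are cut
  into overlapping windows (default 400 bp with 100 bp overlap) and each
  window becomes a column carrying its parent's taxon; shorter sequences are
  excluded.  Splitting lets a single taxon span several columns, which the
  greedy pursuit estimator exploits, and column weights are summed per taxon
  afterwards.

Taxon labels may carry a semicolon-delimited lineage (e.g.
``Bacteria;Proteobacteria;...;Escherichia``); compositions can then be
re-aggregated at a coarser rank such as genus for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from . import kmers
from .errors import (
    EmptyReferenceError,
    InvalidParametersError,
    MissingTaxonError,
    ZeroEstimateError,
)


@dataclass
class TaxonomyMap:
    """Maps reference sequence IDs to taxon labels, optionally with lineages.

    ``entries`` maps sequence ID -> taxon label.  ``lineage`` maps taxon ->
    ordered rank labels from coarsest to finest; the last element is the
    taxon label itself.
    """

    entries: dict[str, str]
    lineage: dict[str, list[str]] = field(default_factory=dict)

    def taxon_of(self, seq_id: str) -> str:
        try:
            return self.entries[seq_id]
        except KeyError:
            raise MissingTaxonError(f"sequence {seq_id!r} missing from taxonomy")

    def rank_label(self, taxon: str, depth_from_end: int = 2) -> str:
        """Label at ``depth_from_end`` ranks above the leaf (2 = genus when
        the lineage ends ...;genus;species).  Falls back to the taxon itself
        when no lineage is recorded."""
        lin = self.lineage.get(taxon)
        if not lin or len(lin) < depth_from_end:
            return taxon
        return lin[-depth_from_end]


@dataclass
class CompositionEstimate:
    """A probability vector over M taxa: nonnegative, summing to one."""

    taxa: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.taxa),):
            raise ValueError("taxa/p length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.taxa, self.p.tolist()))


@dataclass
class ReferenceMatrix:
    """Design matrix of reference k-mer profiles.

    ``columns`` is 4^k x N_cols; ``column_taxa[j]`` indexes into ``taxa`` and
    gives the taxon of column j.  Every taxon owns at least one column.
    """

    columns: np.ndarray
    column_taxa: np.ndarray
    taxa: list[str]
    k: int
    taxonomy: TaxonomyMap | None = None
    meta: dict = field(default_factory=dict)  # build mode and parameters

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        self.column_taxa = np.asarray(self.column_taxa, dtype=int)

    @property
    def n_cols(self) -> int:
        return self.columns.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def save(self, path) -> None:
        """Cache to an NPZ container recording k and the column->taxon map."""
        import json

        np.savez(
            path,
            columns=self.columns,
            column_taxa=self.column_taxa,
            taxa=np.asarray(self.taxa, dtype=object),
            k=self.k,
            meta=json.dumps(self.meta),
        )

    @classmethod
    def load(cls, path) -> "ReferenceMatrix":
        import json

        data = np.load(path, allow_pickle=True)
        return cls(
            columns=data["columns"],
            column_taxa=data["column_taxa"],
            taxa=[str(t) for t in data["taxa"]],
            k=int(data["k"]),
            meta=json.loads(str(data["meta"])) if "meta" in data else {},
        )


def split_sequence(sequence: str, window: int, overlap: int) -> list[str]:
    """Cut a sequence into windows of ``window`` bp overlapping by ``overlap``.

    Window starts advance by ``window - overlap``.  A trailing remainder
    shorter than a full window is kept only when it is at least ``overlap``
    long, so no tail longer than the overlap is silently lost.
    """
    if overlap < 0 or window <= overlap:
        raise InvalidParametersError(
            f"need window > overlap >= 0, got window={window}, overlap={overlap}"
        )
    step = window - overlap
    n = len(sequence)
    pieces: list[str] = []
    start = 0
    while True:
        piece = sequence[start : start + window]
        if len(piece) == window:
            pieces.append(piece)
        else:
            # final shorter remainder: kept only when at least overlap long
            if piece and len(piece) >= overlap:
                pieces.append(piece)
            break
        if start + window >= n:
            break
        start += step
    return pieces


def build_reference(
    fasta_records: Iterable[tuple[str, str]],
    taxonomy: TaxonomyMap,
    k: int,
    mode: str = "whole",
    window: int = 400,
    overlap: int = 100,
    min_length: int = 700,
) -> ReferenceMatrix:
    """Build the estimator design matrix from ``(id, sequence)`` records.

    mode='whole': one profile column per record.  mode='split': records
    strictly longer than ``min_length`` are windowed via
    :func:`split_sequence`; each window becomes a column with the parent's
    taxon; records of length <= ``min_length`` are excluded.
    """
    if mode not in ("whole", "split"):
        raise InvalidParametersError(f"unknown mode {mode!r}")
    cols: list[np.ndarray] = []
    col_taxa: list[str] = []
    for seq_id, seq in fasta_records:
        taxon = taxonomy.taxon_of(seq_id)
        if mode == "whole":
            pieces = [seq]
        else:
            if len(seq) <= min_length:
                continue
            pieces = split_sequence(seq, window, overlap)
        for piece in pieces:
            cols.append(kmers.profile(piece, k).values)
            col_taxa.append(taxon)
    if not cols:
        raise EmptyReferenceError("no reference columns survived construction")
    taxa = sorted(set(col_taxa))
    taxon_index = {t: i for i, t in enumerate(taxa)}
    return ReferenceMatrix(
        columns=np.column_stack(cols),
        column_taxa=np.asarray([taxon_index[t] for t in col_taxa], dtype=int),
        taxa=taxa,
        k=k,
        taxonomy=taxonomy,
        meta={"mode": mode, "window": window, "overlap": overlap,
              "min_length": min_length},
    )


def aggregate_columns_to_taxa(
    column_weights: np.ndarray, ref: ReferenceMatrix
) -> CompositionEstimate:
    """Sum column weights per taxon and renormalize to a composition."""
    w = np.asarray(column_weights, dtype=float)
    if w.shape != (ref.n_cols,):
        raise ValueError(f"expected {ref.n_cols} weights, got {w.shape}")
    if np.any(w < 0):
        raise ValueError("column weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ZeroEstimateError("all column weights are zero")
    per_taxon = np.bincount(ref.column_taxa, weights=w, minlength=ref.n_taxa)
    return CompositionEstimate(list(ref.taxa), per_taxon / total)


def aggregate_to_rank(
    estimate: CompositionEstimate,
    taxonomy: TaxonomyMap,
    depth_from_end: int = 2,
) -> CompositionEstimate:
    """Re-sum a composition at a coarser lineage rank (default: genus).

    Taxa mapping to the same rank label pool their mass; taxa without a
    recorded lineage keep their own label.
    """
    groups: dict[str, float] = {}
    for taxon, mass in zip(estimate.taxa, estimate.p):
        label = taxonomy.rank_label(taxon, depth_from_end)
        groups[label] = groups.get(label, 0.0) + float(mass)
    labels = sorted(groups)
    return CompositionEstimate(labels, np.asarray([groups[t] for t in labels]))
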