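"""File I/O: FASTA/FASTQ reads, taxonomy tables, composition profiles.

Sequence parsing is delegated to Biopython's SeqIO; this module adds format
auto-detection, gzip transparency, and the package's error taxonomy.
Profiles are plain TSV (taxon, proportion) so they diff and version well.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, EmptyInputError, ParseError
from .reference import CompositionEstimate, TaxonomyMap


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: ID, sequence, optional Sanger quality string."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id or not self.sequence:
            raise ParseError("read records need a non-empty id and sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(f"quality/sequence length mismatch in {self.id!r}")


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path: str | Path, format: str = "auto") -> Iterator[ReadRecord]:
    """Stream reads from FASTA or FASTQ, gzip-transparent.

    ``format='auto'`` detects by the first character ('>' FASTA, '@' FASTQ).
    Malformed records raise :class:`ParseError`; an empty file raises
    :class:`EmptyInputError`.
    """
    path = Path(path)
    if format == "auto":
        with _open_text(path) as fh:
            first = fh.read(1)
        if first == ">":
            format = "fasta"
        elif first == "@":
            format = "fastq"
        elif first == "":
            raise EmptyInputError(f"{path} is empty")
        else:
            raise ParseError(f"{path}: cannot detect format from leading {first!r}")
    if format not in ("fasta", "fastq"):
        raise ParseError(f"unsupported format {format!r}")

    count = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, format):
                qual = None
                if format == "fastq":
                    scores = rec.letter_annotations["phred_quality"]
                    qual = "".join(chr(s + 33) for s in scores)
                count += 1
                yield ReadRecord(rec.id, str(rec.seq), qual)
        except ValueError as exc:  # Biopython's malformed-record signal
            raise ParseError(f"{path}, after record {count}: {exc}") from exc
    if count == 0:
        raise EmptyInputError(f"{path} contains no records")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{seq}\n")


def write_fastq(
    records: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I"
) -> None:
    """FASTQ with a constant quality (the simulator carries no base qualities)."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f"@{rec_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """2-column TSV: sequence-ID <tab> semicolon-delimited lineage.

    The last lineage field is the taxon label; the full lineage is retained
    for rank-level (e.g. genus) aggregation.
    """
    entries: dict[str, str] = {}
    lineage: dict[str, list[str]] = {}
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1]:
                raise ParseError(f"{path}:{lineno}: expected 'id<TAB>lineage'")
            seq_id, lin = parts
            ranks = [r.strip() for r in lin.split(";") if r.strip()]
            if not ranks:
                raise ParseError(f"{path}:{lineno}: empty lineage")
            entries[seq_id] = ranks[-1]
            if len(ranks) > 1:
                lineage[ranks[-1]] = ranks
    if not entries:
        raise EmptyInputError(f"{path} contains no taxonomy entries")
    return TaxonomyMap(entries, lineage)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, taxon in taxonomy.entries.items():
            lin = taxonomy.lineage.get(taxon, [taxon])
            fh.write(f"{seq_id}\t{';'.join(lin)}\n")


def write_profile(estimate: CompositionEstimate, path: str | Path) -> None:
    """TSV (taxon, proportion), 10 significant digits, rows sorted by
    descending proportion then taxon label."""
    if not estimate.taxa:
        raise ValueError("refusing to write an empty composition")
    order = sorted(
        range(len(estimate.taxa)), key=lambda i: (-estimate.p[i], estimate.taxa[i])
    )
    with open(path, "w") as fh:
        fh.write("taxon\tproportion\n")
        for i in order:
            fh.write(f"{estimate.taxa[i]}\t{estimate.p[i]:.10g}\n")


def read_profile(path: str | Path) -> CompositionEstimate:
    taxa: list[str] = []
    props: list[float] = []
    with _open_text(Path(path)) as fh:
        header = fh.readline()
        if not header.startswith("taxon"):
            raise ParseError(f"{path}: missing 'taxon<TAB>proportion' header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            taxa.append(parts[0])
            try:
                props.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad proportion") from exc
    if not taxa:
        raise EmptyInputError(f"{path} contains no profile rows")
    return CompositionEstimate(taxa, np.asarray(props))


def align_union(
    p: CompositionEstimate, q: CompositionEstimate
) -> tuple[CompositionEstimate, CompositionEstimate]:
    """Re-express two compositions over the sorted union of their taxa,
    padding missing taxa with zero mass."""
    union = sorted(set(p.taxa) | set(q.taxa))
    if not union:
        raise AlignmentError("no taxa to align")
    pd, qd = p.as_dict(), q.as_dict()
    return (
        CompositionEstimate(union, np.asarray([pd.get(t, 0.0) for t in union])),
        CompositionEstimate(union, np.asarray([qd.get(t, 0.0) for t in union])),
    )


def evaluate_profiles(
    truth_path: str | Path,
    estimate_path: str | Path,
    level: str = "taxon",
    taxonomy: TaxonomyMap | None = None,
) -> dict:
    """Score an estimated profile against a truth profile by VD.

    Profiles are aligned over the union of their taxa (absent taxa get zero
    mass), so the two files need not share support.  ``level='genus'``
    re-sums both profiles at the genus rank first, which requires a
    taxonomy with lineages.
    """
    from .metrics import variational_distance
    from .reference import aggregate_to_rank

    truth = read_profile(truth_path)
    est = read_profile(estimate_path)
    if level == "genus":
        if taxonomy is None:
            raise AlignmentError("genus-level evaluation needs a taxonomy")
        truth = aggregate_to_rank(truth, taxonomy)
        est = aggregate_to_rank(est, taxonomy)
    elif level != "taxon":
        raise ValueError(f"unknown level {level!r}")
    truth_a, est_a = align_union(truth, est)
    return {
        "level": level,
        "vd": variational_distance(truth_a, est_a),
        "n_taxa": len(truth_a.taxa),
    }


def write_sidecar(payload: dict, path: str | Path) -> None:
    """JSON sidecar recording seeds, Q, P and the convergence trace."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
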