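"""Synthetic 16S-like community simulator.

Generates a reference database of random taxa, draws a ground-truth
composition from one of three abundance laws (power law, uniform, linear),
and samples reads from the references with substitution errors and optional
chimeras (two-parent, single-breakpoint artifacts typical of amplicon PCR).
The true composition travels with the reads, so estimation accuracy can be
scored by variational distance without any external data.

The error model is substitution-only: each base is flipped to a uniformly
chosen different base with a fixed per-base probability.  Homopolymer
(454-style flowgram) noise, PCR copy-number bias and length bias are not
modeled; see the methods note for what this implies for transferability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InvalidConfigError
from .reference import CompositionEstimate, TaxonomyMap

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixedLength:
    """All reads share one length (amplicon-like), default 250 bp."""

    length: int = 250


@dataclass(frozen=True)
class NormalLength:
    """Read lengths ~ Normal(mean, sd), rounded and truncated to
    [min_length, reference length].  Defaults mean 450 bp, variance 50 bp^2
    (sd ~ 7.07); pass sd=50 for the sd-of-50 reading."""

    mean: float = 450.0
    sd: float = math.sqrt(50.0)
    min_length: int = 6


ReadLengthModel = FixedLength | NormalLength


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic sample."""

    M_taxa: int = 50
    ref_length: int = 1500
    abundance_law: str = "power_law"  # power_law | uniform | linear
    depth: int = 10_000
    read_length_model: ReadLengthModel = field(default_factory=FixedLength)
    error_rate: float = 0.0
    chimera_rate: float = 0.0
    seed: int = 0
    power_law_alpha: float = 1.0
    family_size: int = 1  # taxa per correlated family (1 = unrelated taxa)
    backbone_share: float = 0.8  # sequence fraction shared within a family

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise InvalidConfigError("depth must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise InvalidConfigError("error_rate must lie in [0, 1)")
        if not (0.0 <= self.chimera_rate < 1.0):
            raise InvalidConfigError("chimera_rate must lie in [0, 1)")
        if self.abundance_law not in ("power_law", "uniform", "linear"):
            raise InvalidConfigError(f"unknown law {self.abundance_law!r}")


@dataclass
class SimulatedSample:
    """Reads plus everything needed to score an estimate against the truth."""

    reads: list[tuple[str, str]]
    truth: CompositionEstimate  # realized pre-chimera taxon draw frequencies
    target: CompositionEstimate  # the abundance vector reads were drawn from
    reference: list[tuple[str, str]]
    taxonomy: TaxonomyMap
    config: SimulationConfig
    chimera_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_chimeras(self) -> int:
        return int(self.chimera_flags.sum())


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def make_reference(
    M: int,
    length: int = 1500,
    seed: int = 0,
    family_size: int = 1,
    backbone_share: float = 0.8,
) -> tuple[list[tuple[str, str]], TaxonomyMap]:
    """Random reference sequences with a taxonomy map.

    With ``family_size > 1`` taxa are grouped into families that share
    ``backbone_share`` of their positions (emulating related taxa within a
    genus); the family labels a genus rank in each taxon's lineage.
    Deterministic per seed.
    """
    if M < 1 or length < 1:
        raise InvalidConfigError("need M >= 1 and length >= 1")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    entries: dict[str, str] = {}
    lineage: dict[str, list[str]] = {}
    fam_size = max(1, family_size)
    n_families = (M + fam_size - 1) // fam_size
    m = 0
    for fam in range(n_families):
        backbone = _random_seq(rng, length)
        genus = f"genus_{fam + 1:04d}"
        for _ in range(min(fam_size, M - m)):
            taxon = f"taxon_{m + 1:04d}"
            if fam_size == 1:
                seq = backbone
            else:
                seq = backbone.copy()
                free = rng.random(length) >= backbone_share
                seq[free] = _random_seq(rng, int(free.sum()))
            seq_id = f"ref_{m + 1:04d}"
            records.append((seq_id, seq.tobytes().decode("ascii")))
            entries[seq_id] = taxon
            lineage[taxon] = ["root", genus, taxon]
            m += 1
    return records, TaxonomyMap(entries, lineage)


def draw_abundances(
    M: int, law: str, seed: int = 0, alpha: float = 1.0
) -> np.ndarray:
    """Ground-truth abundance vector under one of three laws.

    uniform: 1/M each.  linear: proportional to rank 1..M.  power_law:
    proportional to rank^-alpha (alpha = 1 by default).  For the non-uniform
    laws the ranks are randomly permuted over taxa (seeded) so no taxon is
    systematically abundant.
    """
    if M < 1:
        raise InvalidConfigError("M must be >= 1")
    if law == "uniform":
        return np.full(M, 1.0 / M)
    ranks = np.arange(1, M + 1, dtype=float)
    if law == "linear":
        weights = ranks
    elif law == "power_law":
        weights = ranks**-alpha
    else:
        raise InvalidConfigError(f"unknown law {law!r}")
    rng = np.random.default_rng(seed)
    return rng.permutation(weights / weights.sum())


def _draw_length(rng, model: ReadLengthModel, ref_length: int) -> int:
    if isinstance(model, FixedLength):
        if model.length > ref_length:
            raise InvalidConfigError(
                f"read length {model.length} exceeds reference length {ref_length}"
            )
        return model.length
    raw = int(round(rng.normal(model.mean, model.sd)))
    return int(np.clip(raw, model.min_length, ref_length))


def _read_fragment(rng, ref_seq: np.ndarray, length: int) -> np.ndarray:
    start = int(rng.integers(0, len(ref_seq) - length + 1))
    return ref_seq[start : start + length].copy()


def simulate_reads(
    reference: list[tuple[str, str]],
    taxonomy: TaxonomyMap,
    truth: np.ndarray,
    config: SimulationConfig,
) -> SimulatedSample:
    """Sample ``config.depth`` reads from the reference under ``truth``.

    Per read: a taxon is drawn from ``truth`` (this draw defines the
    recorded ground truth); with probability ``chimera_rate`` the read is a
    bimera joining fragments of two distinct parents at a uniform internal
    breakpoint; the read start is uniform over valid positions; each base
    substitutes to a uniform different base with ``error_rate``.
    """
    if isinstance(config.read_length_model, NormalLength):
        if config.read_length_model.mean > config.ref_length:
            raise InvalidConfigError("mean read length exceeds reference length")
    rng = np.random.default_rng(config.seed)
    ref_arrays = [
        np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, seq in reference
    ]
    M = len(reference)
    taxa = [taxonomy.taxon_of(seq_id) for seq_id, _ in reference]
    truth = np.asarray(truth, dtype=float)
    if truth.shape != (M,):
        raise InvalidConfigError("truth length must equal the number of references")

    origins = rng.choice(M, size=config.depth, p=truth)
    is_chimera = rng.random(config.depth) < config.chimera_rate
    reads: list[tuple[str, str]] = []
    for i in range(config.depth):
        length = _draw_length(rng, config.read_length_model, config.ref_length)
        parent = int(origins[i])
        if is_chimera[i] and M > 1:
            other = int(rng.integers(0, M - 1))
            other += other >= parent
            bp = int(rng.integers(1, length))  # breakpoint strictly inside
            left = _read_fragment(rng, ref_arrays[parent], bp)
            right = _read_fragment(rng, ref_arrays[other], length - bp)
            seq = np.concatenate([left, right])
        else:
            seq = _read_fragment(rng, ref_arrays[parent], length)
        if config.error_rate > 0:
            hits = np.flatnonzero(rng.random(length) < config.error_rate)
            if hits.size:
                # substitute to a uniformly chosen *different* base
                shift = rng.integers(1, 4, size=hits.size)
                codes = np.searchsorted(_BASES, seq[hits])
                seq[hits] = _BASES[(codes + shift) % 4]
        reads.append((f"read_{i + 1:06d}", seq.tobytes().decode("ascii")))

    taxa_sorted = sorted(set(taxa))
    idx = {t: j for j, t in enumerate(taxa_sorted)}
    realized = np.zeros(len(taxa_sorted))
    intended = np.zeros(len(taxa_sorted))
    for m in range(M):
        intended[idx[taxa[m]]] += truth[m]
    counts = np.bincount(origins, minlength=M)
    for m in range(M):
        realized[idx[taxa[m]]] += counts[m]
    realized /= config.depth
    return SimulatedSample(
        reads=reads,
        truth=CompositionEstimate(taxa_sorted, realized),
        target=CompositionEstimate(taxa_sorted, intended),
        reference=reference,
        taxonomy=taxonomy,
        config=config,
        chimera_flags=is_chimera & (M > 1),
    )


def simulate_sample(config: SimulationConfig) -> SimulatedSample:
    """End-to-end convenience: reference, abundances, reads, truth."""
    records, taxonomy = make_reference(
        config.M_taxa,
        config.ref_length,
        config.seed,
        config.family_size,
        config.backbone_share,
    )
    truth = draw_abundances(
        config.M_taxa, config.abundance_law, config.seed, config.power_law_alpha
    )
    return simulate_reads(records, taxonomy, truth, config)


def write_sample(sample: SimulatedSample, outdir: str | Path) -> dict[str, Path]:
    """Write reads (FASTA), reference (FASTA), taxonomy (TSV) and truth (TSV)."""
    from . import io as ark_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.fasta",
        "reference": outdir / "reference.fasta",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "truth.tsv",
    }
    ark_io.write_fasta(sample.reads, paths["reads"])
    ark_io.write_fasta(sample.reference, paths["reference"])
    ark_io.write_taxonomy(sample.taxonomy, paths["taxonomy"])
    ark_io.write_profile(sample.truth, paths["truth"])
    return paths
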