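"""Gene regions, trinucleotide indexing, and SNV-to-gene assignment.

A *gene region* is the genomic span of a gene's canonical transcript
extended by a fixed flank on both sides (10 kb total by default), the
interval over which somatic SNVs are collected and permuted.  Each region
carries its reference sequence with a one-base margin on either side so
that every in-region position has a fully determined trinucleotide window
(5' neighbour, the base itself, 3' neighbour, read on the forward strand).

Coordinates are 1-based inclusive throughout, matching VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: the 64 forward-strand reference trinucleotides
TRINUCLEOTIDES = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


@dataclass(frozen=True)
class SNV:
    """One somatic single-nucleotide substitution observed in one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(
                f"SNV at {self.chrom}:{self.pos} has non-ACGT alleles "
                f"{self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise ValueError(f"SNV at {self.chrom}:{self.pos}: ref == alt ({self.ref})")
        if self.pos < 1:
            raise ValueError(f"SNV position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Transcript:
    """Canonical-transcript record from an annotation source (1-based inclusive)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    is_protein_coding: bool = True


@dataclass
class GeneRegion:
    """Canonical transcript span +/- flank with its margin-padded sequence.

    ``sequence`` covers ``[start - 1, end + 1]`` so positions ``start..end``
    all have a centred 3-mer; bases outside the chromosome are padded 'N'.
    """

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    is_protein_coding: bool = True

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start ({self.end} < {self.start})")
        expected = (self.end - self.start + 1) + 2
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"region length + 2 margins ({expected})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def base_at(self, pos: int) -> str:
        """Reference base at a 1-based genomic position inside the region."""
        if not self.contains(pos):
            raise IndexError(f"position {pos} outside region [{self.start}, {self.end}]")
        return self.sequence[pos - self.start + 1]

    def trinucleotide_at(self, pos: int) -> str:
        """Forward-strand 3-mer centred on ``pos`` (may contain N at edges)."""
        if not self.contains(pos):
            raise IndexError(f"position {pos} outside region [{self.start}, {self.end}]")
        i = pos - self.start + 1
        return self.sequence[i - 1 : i + 2]


@dataclass
class TrinucleotideIndex:
    """Per-region buckets: reference 3-mer -> sorted in-region positions.

    Every in-region position whose centred window is N-free appears in
    exactly one bucket; N-window positions are excluded.
    """

    gene_id: str
    buckets: dict[str, np.ndarray]
    n_excluded: int = 0

    def bucket(self, trinucleotide: str) -> np.ndarray:
        return self.buckets.get(trinucleotide, np.empty(0, dtype=np.int64))

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.buckets.values())


@dataclass
class GeneAssignment:
    """gene_id -> sample_id -> list of SNVs contained in that gene's region.

    An SNV overlapping k regions is assigned to all k genes.
    """

    by_gene: dict[str, dict[str, list[SNV]]] = field(default_factory=dict)
    rejects: list[tuple[SNV, str]] = field(default_factory=list)
    n_unassigned: int = 0

    def samples_of(self, gene_id: str) -> dict[str, list[SNV]]:
        return self.by_gene.get(gene_id, {})

    def n_snvs(self, gene_id: str) -> int:
        return sum(len(v) for v in self.samples_of(gene_id).values())

    def n_mutated_samples(self, gene_id: str) -> int:
        return sum(1 for v in self.samples_of(gene_id).values() if v)


class SequenceSource:
    """Minimal protocol for reference access: dict of chrom -> sequence or
    a pyfaidx.Fasta both work (must support ``source[chrom]`` slicing and
    ``len``)."""


def _fetch_padded(genome, chrom: str, start: int, end: int, chrom_len: int) -> str:
    """Sequence for 1-based inclusive [start, end], N-padded outside [1, chrom_len]."""
    left_pad = max(0, 1 - start)
    right_pad = max(0, end - chrom_len)
    lo = max(start, 1)
    hi = min(end, chrom_len)
    seq = str(genome[chrom][lo - 1 : hi])
    return "N" * left_pad + seq.upper() + "N" * right_pad


def _chrom_length(genome, chrom: str) -> int:
    rec = genome[chrom]
    return len(rec)


def build_gene_regions(
    transcripts: Iterable[Transcript],
    genome,
    flank: int = 5000,
) -> list[GeneRegion]:
    """Build one flanked, sequence-backed region per protein-coding gene.

    Parameters
    ----------
    transcripts
        One canonical transcript per gene.
    genome
        Mapping chrom -> sliceable sequence (``pyfaidx.Fasta`` or a plain
        dict of strings).
    flank
        Bases added on both sides of the transcript span, regardless of
        strand.  Bounds are clipped at chromosome ends.
    """
    regions: list[GeneRegion] = []
    n_skipped_noncoding = 0
    for tx in transcripts:
        if tx.end < tx.start:
            raise ValueError(
                f"transcript for gene {tx.gene_id} has end < start "
                f"({tx.end} < {tx.start})"
            )
        try:
            chrom_len = _chrom_length(genome, tx.chrom)
        except KeyError as exc:
            raise KeyError(
                f"chromosome {tx.chrom!r} (gene {tx.gene_id}) absent from reference"
            ) from exc
        if not tx.is_protein_coding:
            n_skipped_noncoding += 1
            continue
        start = max(1, tx.start - flank)
        end = min(chrom_len, tx.end + flank)
        seq = _fetch_padded(genome, tx.chrom, start - 1, end + 1, chrom_len)
        regions.append(
            GeneRegion(
                gene_id=tx.gene_id,
                gene_name=tx.gene_name,
                chrom=tx.chrom,
                start=start,
                end=end,
                strand=tx.strand,
                sequence=seq,
            )
        )
    if n_skipped_noncoding:
        logger.info("skipped %d non-protein-coding transcripts", n_skipped_noncoding)
    return regions


def index_trinucleotides(region: GeneRegion) -> TrinucleotideIndex:
    """Bucket every in-region position by its centred forward-strand 3-mer.

    Positions whose window contains a non-ACGT base fall in no bucket; their
    count is recorded (and logged) rather than raising.
    """
    seq = region.sequence
    buckets: dict[str, list[int]] = {}
    n_excluded = 0
    for offset in range(1, len(seq) - 1):
        tri = seq[offset - 1 : offset + 2]
        if set(tri) <= VALID_BASES:
            buckets.setdefault(tri, []).append(region.start + offset - 1)
        else:
            n_excluded += 1
    if n_excluded:
        logger.debug(
            "%s: %d positions excluded from trinucleotide index (N windows)",
            region.gene_id,
            n_excluded,
        )
    arrays = {k: np.asarray(v, dtype=np.int64) for k, v in buckets.items()}
    return TrinucleotideIndex(gene_id=region.gene_id, buckets=arrays, n_excluded=n_excluded)


def assign_snvs(snvs: Sequence[SNV], regions: Sequence[GeneRegion]) -> GeneAssignment:
    """Assign SNVs to every gene region containing their position.

    SNVs falling in no region are dropped (count logged); SNVs whose ref
    base disagrees with the region sequence are rejected and reported in
    ``assignment.rejects``, never assigned.
    """
    assignment = GeneAssignment()
    by_chrom: dict[str, list[GeneRegion]] = {}
    for region in regions:
        assignment.by_gene.setdefault(region.gene_id, {})
        by_chrom.setdefault(region.chrom, []).append(region)

    rejected_keys: set[tuple[str, int, str, str, str]] = set()
    for snv in snvs:
        hit = False
        for region in by_chrom.get(snv.chrom, ()):
            if not region.contains(snv.pos):
                continue
            if region.base_at(snv.pos) != snv.ref:
                k = (*snv.key, snv.sample_id)
                if k not in rejected_keys:
                    rejected_keys.add(k)
                    assignment.rejects.append((snv, "reference_mismatch"))
                continue
            hit = True
            assignment.by_gene[region.gene_id].setdefault(snv.sample_id, []).append(snv)
        if not hit:
            assignment.n_unassigned += 1
    if assignment.n_unassigned:
        logger.info(
            "%d SNVs fell outside all gene regions or were rejected",
            assignment.n_unassigned,
        )
    if assignment.rejects:
        logger.warning(
            "%d SNVs rejected for reference-base mismatch", len(assignment.rejects)
        )
    return assignment
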