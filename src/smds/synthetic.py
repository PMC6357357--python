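"""Self-contained synthetic cohorts with known driver ground truth.

The generator emulates the structure of a somatic-SNV cohort at desk
scale: each gene lives on its own contig with a transcript span flanked on
both sides; passenger SNVs are drawn per sample from a trinucleotide
substitution signature (a probability over 192 literal forward-strand
context x substitution classes; a 96-class pyrimidine-centred signature is
accepted and expanded symmetrically); driver genes additionally carry, in a
carrier fraction of samples, one SNV at a designated high-scoring site.
Score systems assign the driver-site variant a draw from a high
(driver) distribution and every other in-region variant a draw from a
background (passenger) distribution, with an optional missingness fraction
emulating missense-only predictors.  All randomness is keyed off the spec
seed, so the same spec reproduces byte-identical outputs.

Score values are produced by a keyed hash (BLAKE2), making every possible
in-region variant scorable without materialising a table; writing the
cohort to disk enumerates the same function into a plain score TSV, so the
file-based and in-memory routes agree exactly.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    SNV,
    GeneRegion,
    TrinucleotideIndex,
    index_trinucleotides,
)
from .scoring import ScoreSet

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: the 192 literal forward-strand (trinucleotide, alt) mutation classes
MUTATION_CLASSES: tuple[tuple[str, str], ...] = tuple(
    (a + b + c, alt)
    for a in BASES
    for b in BASES
    for c in BASES
    for alt in BASES
    if alt != b
)

#: the 96 pyrimidine-centred classes in conventional order
PYRIMIDINE_CLASSES: tuple[tuple[str, str], ...] = tuple(
    (a + b + c, alt)
    for b in "CT"
    for alt in BASES
    if alt != b
    for a in BASES
    for c in BASES
)


def expand_signature(signature_96: Mapping[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    """Expand a 96-class pyrimidine-centred signature to 192 literal classes.

    Each pyrimidine-centred class splits its mass equally between the
    literal class and its reverse complement.
    """
    out: dict[tuple[str, str], float] = {}
    for (tri, alt), p in signature_96.items():
        if tri[1] not in "CT":
            raise ValueError(f"96-class signature must be pyrimidine-centred, got {tri}")
        rc_tri = tri.translate(COMPLEMENT)[::-1]
        rc_alt = alt.translate(COMPLEMENT)
        out[(tri, alt)] = out.get((tri, alt), 0.0) + p / 2.0
        out[(rc_tri, rc_alt)] = out.get((rc_tri, rc_alt), 0.0) + p / 2.0
    return out


def default_signature() -> dict[tuple[str, str], float]:
    """Mildly transition-skewed 192-class signature.

    C>T (and its complement G>A) substitutions get three times the weight
    of the other classes, a crude caricature of the deamination-dominated
    signatures seen in most tumours.
    """
    weights = {}
    for tri, alt in MUTATION_CLASSES:
        ref = tri[1]
        w = 3.0 if (ref, alt) in (("C", "T"), ("G", "A")) else 1.0
        weights[(tri, alt)] = w
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


@dataclass(frozen=True)
class ScoreSpec:
    """One synthetic scoring system's behaviour."""

    name: str
    missingness: float = 0.0  # fraction of variants absent from the table
    passenger_low: float = 0.0
    passenger_high: float = 1.0
    driver_low: float = 0.9
    driver_high: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic somatic-SNV cohort.

    Defaults describe a small but non-trivial cohort: 50 samples, 50 genes
    of 1-3 kb with 1 kb flanks, ten driver genes each mutated at a single
    high-scoring site in 40% of samples, one passenger SNV per sample per
    gene region on average, and passenger scores uniform below 0.3 against
    driver scores in [0.9, 1].
    """

    n_genes: int = 50
    n_driver_genes: int = 10
    gene_length: tuple[int, int] = (1000, 3000)
    flank: int = 1000
    gc_content: float = 0.45
    n_samples: int = 50
    snvs_per_gene_per_sample: float = 1.0  # Poisson mean over the gene region
    carrier_fraction: float = 0.4
    signature: Mapping[tuple[str, str], float] | None = None
    score_specs: tuple[ScoreSpec, ...] = (
        ScoreSpec("pan_a", missingness=0.0, passenger_high=0.3),
        ScoreSpec("pan_b", missingness=0.0, passenger_high=0.3),
        ScoreSpec("missense_like", missingness=0.6, passenger_high=0.3),
    )
    seed: int = 0

    def resolved_signature(self) -> dict[tuple[str, str], float]:
        if self.signature is None:
            return default_signature()
        sig = dict(self.signature)
        if all(tri[1] in "CT" for tri, _ in sig):
            sig = expand_signature(sig)
        total = sum(sig.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"signature probabilities sum to {total}, not 1")
        return sig


@dataclass
class SyntheticCohort:
    """In-memory view of a generated cohort, ready for the pipeline."""

    spec: CohortSpec
    regions: list[GeneRegion]
    indexes: dict[str, TrinucleotideIndex]
    snvs: list[SNV]
    score_sets: dict[str, ScoreSet]
    driver_genes: list[str]
    driver_sites: dict[str, SNV]  # gene_id -> the designated driver variant
    contigs: dict[str, str] = field(default_factory=dict)


def _hash_unit(*parts) -> float:
    """Deterministic uniform(0,1) value keyed by the given parts."""
    h = hashlib.blake2b("\x1f".join(map(str, parts)).encode(), digest_size=8)
    return struct.unpack(">Q", h.digest())[0] / 2.0**64


def _make_score_lookup(
    spec: CohortSpec, sspec: ScoreSpec, driver_sites: Mapping[str, SNV]
):
    driver_keys = {snv.key: gene for gene, snv in driver_sites.items()}

    def lookup(chrom: str, pos: int, ref: str, alt: str):
        key = (chrom, pos, ref, alt)
        if key in driver_keys:
            u = _hash_unit(spec.seed, sspec.name, "driver", *key)
            return sspec.driver_low + u * (sspec.driver_high - sspec.driver_low)
        if sspec.missingness > 0.0:
            if _hash_unit(spec.seed, sspec.name, "miss", *key) < sspec.missingness:
                return None
        u = _hash_unit(spec.seed, sspec.name, "score", *key)
        return sspec.passenger_low + u * (sspec.passenger_high - sspec.passenger_low)

    return lookup


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort according to ``spec`` (deterministic in spec.seed).

    Passenger SNVs: per (sample, gene) a Poisson count of SNVs, each drawn
    by sampling a mutation class from the signature (renormalised over the
    classes whose trinucleotide occurs in the gene) and then a uniform
    position within the matching context bucket.  Driver SNVs: each driver
    gene gets one designated site; a carrier subset of samples receives
    that exact variant.
    """
    rng = np.random.default_rng([int(spec.seed) % 2**31, 0x5EED])
    signature = spec.resolved_signature()
    classes = list(signature)
    class_p = np.array([signature[c] for c in classes])

    regions: list[GeneRegion] = []
    indexes: dict[str, TrinucleotideIndex] = {}
    contigs: dict[str, str] = {}
    for gi in range(spec.n_genes):
        length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
        contig_len = length + 2 * spec.flank + 2
        gene_id = f"GENE{gi:04d}"
        seq = _random_sequence(rng, contig_len, spec.gc_content)
        contigs[gene_id] = seq
        tx_start, tx_end = spec.flank + 2, spec.flank + 1 + length
        start, end = tx_start - spec.flank, tx_end + spec.flank  # = [2, contig_len - 1]
        region = GeneRegion(
            gene_id=gene_id,
            gene_name=gene_id,
            chrom=gene_id,
            start=start,
            end=end,
            strand="+" if rng.random() < 0.5 else "-",
            sequence=seq[start - 2 : end + 1],
        )
        regions.append(region)
        indexes[gene_id] = index_trinucleotides(region)

    driver_genes = [r.gene_id for r in regions[: spec.n_driver_genes]]

    # designated driver site per driver gene: any in-region position
    driver_sites: dict[str, SNV] = {}
    for gene_id in driver_genes:
        index = indexes[gene_id]
        region = next(r for r in regions if r.gene_id == gene_id)
        all_pos = np.sort(np.concatenate(list(index.buckets.values())))
        pos = int(all_pos[rng.integers(0, len(all_pos))])
        ref = region.base_at(pos)
        alt = rng.permutation([b for b in BASES if b != ref])[0]
        driver_sites[gene_id] = SNV(region.chrom, pos, ref, str(alt), sample_id="__site__")

    samples = [f"S{si:03d}" for si in range(spec.n_samples)]
    snvs: list[SNV] = []
    for region in regions:
        index = indexes[region.gene_id]
        present = [c for c in classes if len(index.bucket(c[0])) > 0]
        if not present:
            raise RuntimeError(f"{region.gene_id}: no signature context present")
        p = np.array([signature[c] for c in present])
        p = p / p.sum()
        for sample in samples:
            n = rng.poisson(spec.snvs_per_gene_per_sample)
            if n == 0:
                continue
            drawn = rng.choice(len(present), size=n, p=p)
            for ci in drawn:
                tri, alt = present[ci]
                bucket = index.bucket(tri)
                pos = int(bucket[rng.integers(0, len(bucket))])
                snvs.append(SNV(region.chrom, pos, tri[1], alt, sample_id=sample))

    for gene_id in driver_genes:
        site = driver_sites[gene_id]
        n_carriers = max(1, round(spec.carrier_fraction * spec.n_samples))
        carriers = rng.choice(spec.n_samples, size=n_carriers, replace=False)
        for si in sorted(carriers):
            snvs.append(replace(site, sample_id=samples[si]))

    score_sets = {
        sspec.name: ScoreSet(
            name=sspec.name,
            lookup=_make_score_lookup(spec, sspec, driver_sites),
            rescale_mode="none",
        )
        for sspec in spec.score_specs
    }
    return SyntheticCohort(
        spec=spec,
        regions=regions,
        indexes=indexes,
        snvs=snvs,
        score_sets=score_sets,
        driver_genes=driver_genes,
        driver_sites=driver_sites,
        contigs=contigs,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the pipeline's input formats.

    Emits reference FASTA, GFF3 annotation (one canonical protein-coding
    transcript per gene), SNV TSV (chrom, pos, ref, alt, sample_id), one
    score TSV per scoring system (enumerating every non-missing in-region
    variant), and the plain-text truth gene list.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "reference.fa"
    with fasta.open("w") as fh:
        for name, seq in cohort.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    paths["fasta"] = fasta

    gff = outdir / "annotation.gff3"
    flank = cohort.spec.flank
    with gff.open("w") as fh:
        fh.write("##gff-version 3\n")
        for region in cohort.regions:
            tx_start, tx_end = region.start + flank, region.end - flank
            attrs_gene = f"ID={region.gene_id};Name={region.gene_name};biotype=protein_coding"
            attrs_tx = (
                f"ID={region.gene_id}.t1;Parent={region.gene_id};"
                f"Name={region.gene_name};biotype=protein_coding;canonical=1"
            )
            fh.write(
                f"{region.chrom}\tsmds\tgene\t{tx_start}\t{tx_end}\t.\t{region.strand}\t.\t{attrs_gene}\n"
            )
            fh.write(
                f"{region.chrom}\tsmds\tmRNA\t{tx_start}\t{tx_end}\t.\t{region.strand}\t.\t{attrs_tx}\n"
            )
    paths["annotation"] = gff

    snv_tsv = outdir / "snvs.tsv"
    pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt, "sample_id": s.sample_id}
            for s in cohort.snvs
        ]
    ).to_csv(snv_tsv, sep="\t", index=False)
    paths["snvs"] = snv_tsv

    for name, score_set in cohort.score_sets.items():
        rows = []
        for region in cohort.regions:
            for pos in range(region.start, region.end + 1):
                ref = region.base_at(pos)
                if ref not in BASES:
                    continue
                for alt in BASES:
                    if alt == ref:
                        continue
                    raw = score_set.raw(region.chrom, pos, ref, alt)
                    if raw is None:
                        continue
                    rows.append((region.chrom, pos, ref, alt, raw))
        path = outdir / f"scores_{name}.tsv"
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "score"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
        paths[f"scores_{name}"] = path

    truth = outdir / "truth_genes.txt"
    truth.write_text("".join(g + "\n" for g in cohort.driver_genes))
    paths["truth"] = truth
    return paths


def truth_metrics(
    candidate_genes: Iterable[str], truth_genes: Iterable[str]
) -> tuple[float, int]:
    """(sensitivity over the truth drivers, count of non-truth candidates)."""
    candidates = {g.upper() for g in candidate_genes}
    truth = {g.upper() for g in truth_genes}
    if not truth:
        raise ValueError("truth gene list is empty")
    sensitivity = len(candidates & truth) / len(truth)
    false_positives = len(candidates - truth)
    return sensitivity, false_positives
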