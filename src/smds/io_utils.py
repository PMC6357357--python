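"""Readers, writers, run configuration and the end-to-end pipeline.

Input formats: FASTA reference (pyfaidx), GFF3 or BED12 gene annotation,
SNVs as VCF (cyvcf2) or a five-column TSV (chrom, pos, ref, alt,
sample_id), tab-delimited score tables, and a plain-text truth gene list.
Outputs are TSVs re-readable by this module's own readers, a Newick
dendrogram, and a JSON run manifest that fully determines a rerun.

Coordinates are 1-based inclusive everywhere (BED converted on read).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .consensus import (
    CandidateSet,
    evaluate_models,
    evaluations_to_frame,
    intersect_models,
    qq_data,
    select_candidates,
)
from .genome_model import (
    SNV,
    GeneRegion,
    Transcript,
    assign_snvs,
    build_gene_regions,
    index_trinucleotides,
)
from .permutation import DEFAULT_TRIALS, GeneTestResult, run_gene_tests
from .scoring import ScoreSet, correlation_matrix, upgma_cluster

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    genome: str
    annotation: str
    snvs: str
    score_tables: dict[str, str]  # score name -> path
    truth_genes: str | None = None
    outdir: str = "smds_out"
    flank: int = 5000
    trials: int = DEFAULT_TRIALS
    alpha: float = 0.01
    seed: int = 0
    rescale_modes: dict[str, str] = field(default_factory=dict)  # name -> none|rank
    position_only: dict[str, bool] = field(default_factory=dict)
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.genome, self.annotation, self.snvs, *self.score_tables.values()]
            + ([self.truth_genes] if self.truth_genes else [])
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


# ---------------------------------------------------------------------------
# readers

def read_snvs_tsv(path: str | Path) -> list[SNV]:
    """Read SNVs from a TSV with columns chrom, pos, ref, alt, sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    required = {"chrom", "pos", "ref", "alt", "sample_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: SNV TSV must have columns {sorted(required)}")
    snvs, n_dropped = [], 0
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref == alt or {ref, alt} - set("ACGT"):
            n_dropped += 1
            continue
        snvs.append(SNV(str(row.chrom), int(row.pos), ref, alt, str(row.sample_id)))
    if n_dropped:
        logger.info("%s: dropped %d non-SNV rows", path, n_dropped)
    return snvs


def read_snvs_vcf(path: str | Path) -> list[SNV]:
    """Read somatic SNVs from a VCF.

    Multi-allelic records are split per ALT allele; non-SNV alleles are
    dropped with a logged count.  With genotyped samples, each sample whose
    genotype carries the allele yields one SNV; a sample-less VCF yields
    SNVs attributed to the record's ID or 'unknown'.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snvs: list[SNV] = []
    n_dropped = 0
    for record in vcf:
        ref = record.REF.upper()
        for ai, alt in enumerate(record.ALT):
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or {ref, alt} - set("ACGT") or ref == alt:
                n_dropped += 1
                continue
            if samples:
                genotypes = record.genotype.array()
                for si, sample in enumerate(samples):
                    # allele index ai+1 anywhere in the genotype calls
                    if (genotypes[si][:-1] == ai + 1).any():
                        snvs.append(SNV(record.CHROM, record.POS, ref, alt, sample))
            else:
                sample = record.ID or "unknown"
                snvs.append(SNV(record.CHROM, record.POS, ref, alt, sample))
    if n_dropped:
        logger.info("%s: dropped %d non-SNV ALT alleles", path, n_dropped)
    return snvs


def read_snvs(path: str | Path, fmt: str | None = None) -> list[SNV]:
    """Dispatch on format ('vcf' or 'tsv'; inferred from the suffix)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if fmt == "vcf":
        return read_snvs_vcf(path)
    if fmt == "tsv":
        return read_snvs_tsv(path)
    raise ValueError(f"unknown SNV format {fmt!r}")


def _gff3_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for item in attr_field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_transcripts_gff3(
    path: str | Path, transcript_ids: Iterable[str] | None = None
) -> list[Transcript]:
    """Canonical transcripts from a GFF3 file.

    Transcript-like features (mRNA/transcript) are kept if flagged
    canonical (attribute ``canonical=1`` or tag) or listed in
    ``transcript_ids``.  Gene identity comes from Parent/ID attributes;
    protein-coding status from a biotype-like attribute (absent -> assumed
    coding).
    """
    wanted = set(transcript_ids) if transcript_ids is not None else None
    transcripts: dict[str, Transcript] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in ("mRNA", "transcript"):
                continue
            a = _gff3_attributes(attrs)
            tx_id = a.get("ID", "")
            canonical = a.get("canonical", a.get("Ensembl_canonical", "")) in ("1", "true", "True")
            if wanted is not None:
                if tx_id not in wanted:
                    continue
            elif not canonical:
                continue
            gene_id = a.get("Parent", tx_id)
            biotype = a.get("biotype", a.get("gene_biotype", "protein_coding"))
            tx = Transcript(
                gene_id=gene_id,
                gene_name=a.get("Name", gene_id),
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand if strand in "+-" else "+",
                is_protein_coding=biotype == "protein_coding",
            )
            if gene_id in transcripts:
                raise ValueError(
                    f"{path}: gene {gene_id} has more than one canonical transcript"
                )
            transcripts[gene_id] = tx
    if not transcripts:
        raise ValueError(f"{path}: no canonical transcripts found")
    return list(transcripts.values())


def read_transcripts_bed12(path: str | Path) -> list[Transcript]:
    """Transcripts from BED12 (0-based half-open converted to 1-based inclusive)."""
    transcripts = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: BED line with fewer than 6 fields")
            chrom, start, end, name, _, strand = fields[:6]
            transcripts.append(
                Transcript(
                    gene_id=name,
                    gene_name=name,
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                )
            )
    return transcripts


def read_transcripts(path: str | Path, transcript_ids=None) -> list[Transcript]:
    if str(path).endswith((".bed", ".bed12")):
        return read_transcripts_bed12(path)
    return read_transcripts_gff3(path, transcript_ids)


def read_score_table(
    path: str | Path,
    name: str,
    rescale_mode: str = "none",
    position_only: bool = False,
) -> ScoreSet:
    """Load a tab-delimited score table into a ScoreSet.

    Expected header: chrom, pos, ref, alt, score — or chrom, pos, score in
    the position-only dialect used for splicing-style systems.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if position_only:
        required = {"chrom", "pos", "score"}
    else:
        required = {"chrom", "pos", "ref", "alt", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: score table must have columns {sorted(required)}")
    if position_only:
        lookup = {
            (str(r.chrom), int(r.pos)): float(r.score) for r in df.itertuples(index=False)
        }
    else:
        lookup = {
            (str(r.chrom), int(r.pos), str(r.ref).upper(), str(r.alt).upper()): float(r.score)
            for r in df.itertuples(index=False)
        }
    return ScoreSet(
        name=name, lookup=lookup, rescale_mode=rescale_mode, position_only=position_only
    )


def read_truth_genes(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line, '#' comments allowed."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                genes.append(line)
    return genes


# ---------------------------------------------------------------------------
# writers

def results_to_frame(results: Sequence[GeneTestResult]) -> pd.DataFrame:
    """Per-gene result table (one score set); p-values also given rounded
    to 3 decimals in a display column, full precision retained."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "gene_name": [r.gene_name for r in results],
            "n_snvs": [r.n_snvs for r in results],
            "n_mutated_samples": [r.n_mutated_samples for r in results],
            "observed_smds": [r.observed_smds for r in results],
            "exceed_count": [r.exceed_count for r in results],
            "trials": [r.trials for r in results],
            "p_value": [round(r.p_value, 3) for r in results],
            "p_value_full": [r.p_value for r in results],
            "p_value_add_one": [r.p_value_add_one for r in results],
            "tested": [r.tested for r in results],
        }
    )
    return df.sort_values(["p_value_full", "gene_id"]).reset_index(drop=True)


def write_rejects(rejects: Sequence[tuple[SNV, str]], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "sample_id": s.sample_id,
                "reason": reason,
            }
            for s, reason in rejects
        ],
        columns=["chrom", "pos", "ref", "alt", "sample_id", "reason"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all outputs under config.outdir.

    Stages: build flanked gene regions; read and assign SNVs (rejects
    written); load and rank-rescale score tables; permutation test per
    (gene, score); candidate selection; cross-model intersection and
    consensus; truth-set overlap and ranking; QQ tables; score correlation
    and UPGMA dendrogram; JSON manifest.  Returns a summary dict.
    """
    import pyfaidx

    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = pyfaidx.Fasta(config.genome)
    transcripts = read_transcripts(config.annotation)
    regions = build_gene_regions(transcripts, genome, flank=config.flank)
    logger.info("built %d gene regions (flank %d)", len(regions), config.flank)

    snvs = read_snvs(config.snvs)
    assignment = assign_snvs(snvs, regions)
    write_rejects(assignment.rejects, outdir / "rejected_snvs.tsv")
    logger.info(
        "read %d SNVs; %d unassigned/rejected", len(snvs), assignment.n_unassigned
    )

    score_sets = []
    observed_keys = sorted({s.key for s in snvs})
    for name, path in config.score_tables.items():
        ss = read_score_table(
            path,
            name,
            rescale_mode=config.rescale_modes.get(name, "none"),
            position_only=config.position_only.get(name, False),
        )
        if ss.rescale_mode == "rank":
            ss.fit_rescaler(observed_keys)
        score_sets.append(ss)

    results = run_gene_tests(
        regions,
        assignment,
        score_sets,
        trials=config.trials,
        global_seed=config.seed,
        n_jobs=config.n_jobs,
    )
    by_score: dict[str, list[GeneTestResult]] = {}
    for r in results:
        by_score.setdefault(r.score_name, []).append(r)
    for name, rs in by_score.items():
        results_to_frame(rs).to_csv(outdir / f"results_{name}.tsv", sep="\t", index=False)

    candidate_sets = [
        select_candidates(rs, alpha=config.alpha) for rs in by_score.values()
    ]
    for cs in candidate_sets:
        pd.DataFrame({"gene_id": sorted(cs.genes)}).to_csv(
            outdir / f"candidates_{cs.score_name}.tsv", sep="\t", index=False
        )

    summary: dict = {
        "n_genes": len(regions),
        "n_snvs": len(snvs),
        "n_unassigned": assignment.n_unassigned,
        "n_rejected": len(assignment.rejects),
        "candidates": {cs.score_name: len(cs) for cs in candidate_sets},
    }

    if len(candidate_sets) >= 2:
        table = intersect_models(candidate_sets)
        table.to_frame().to_csv(outdir / "intersections.tsv", sep="\t", index=False)
        summary["union_candidates"] = table.union_size

    truth = read_truth_genes(config.truth_genes) if config.truth_genes else None
    if len(candidate_sets) >= 3 or truth:
        try:
            evaluations = evaluate_models(candidate_sets, truth_genes=truth)
            evaluations_to_frame(evaluations).to_csv(
                outdir / "evaluation.tsv", sep="\t", index=False
            )
        except ValueError as exc:
            logger.info("evaluation stage skipped: %s", exc)
    else:
        logger.info("fewer than three score sets: consensus evaluation skipped")

    for name, rs in by_score.items():
        tested = [r for r in rs if r.tested]
        if tested:
            qq = qq_data(
                [r.p_value for r in tested],
                score_name=name,
                p_values_for_log=[r.p_value_add_one for r in tested],
            )
            qq.to_frame().to_csv(outdir / f"qq_{name}.tsv", sep="\t", index=False)

    if len(score_sets) >= 2 and len(observed_keys) >= 3:
        vectors = {
            ss.name: [ss.score(*k) for k in observed_keys] for ss in score_sets
        }
        comparison = correlation_matrix(vectors)
        pd.DataFrame(
            comparison.correlation, index=comparison.names, columns=comparison.names
        ).to_csv(outdir / "score_correlation.tsv", sep="\t")
        valid = ~np.isnan(comparison.correlation).any(axis=0)
        if valid.sum() >= 2:
            names = [n for n, v in zip(comparison.names, valid) if v]
            dist = comparison.distance[np.ix_(valid, valid)]
            np.fill_diagonal(dist, 0.0)
            _, newick = upgma_cluster(dist, names)
            (outdir / "score_dendrogram.nwk").write_text(newick + "\n")

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "counts": summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return summary
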