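"""Observed MDS/SMDS statistics and the context-preserving permutation null.

For each gene g, sample s and scoring system c the *most deleterious score*
(MDS) is

    X_gsc = max over the sample's SNVs in the gene of the variant score,

zero when the sample has no scored SNV there.  The gene-level test
statistic is the *sum of most deleterious scores* over the cohort,

    D_gc = sum_s X_gsc.

The null distribution is built within the gene: each observed SNV is moved,
independently per trial, to a position drawn uniformly from the set of
in-region sites sharing its reference trinucleotide (the SNV's own site is
in that set), carrying its ref>alt substitution along; the relocated SNVs
are rescored by table lookup and the statistic recomputed.  With m trials
the empirical p-value is the fraction of null statistics greater than or
equal to the observed one, which can be exactly 0.

Placements are independent draws with replacement, so two SNVs of one
sample may land on the same site; this keeps the null a product measure
and exactly enumerable for small genes.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .genome_model import SNV, GeneAssignment, GeneRegion, TrinucleotideIndex, index_trinucleotides
from .scoring import ScoreSet

logger = logging.getLogger(__name__)

DEFAULT_TRIALS = 1000


@dataclass
class MdsMatrix:
    """(gene, sample) -> most deleterious score for one scoring system."""

    score_name: str
    values: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, gene_id: str, sample_id: str) -> float:
        return self.values.get((gene_id, sample_id), 0.0)


@dataclass
class PermutedPlacement:
    """One trial's relocation of one sample's SNVs within one gene."""

    gene_id: str
    sample_id: str
    moves: list[tuple[SNV, int]]  # (original SNV, new position)


@dataclass
class GeneTestResult:
    """Permutation-test outcome for one gene under one scoring system."""

    gene_id: str
    gene_name: str
    score_name: str
    n_snvs: int
    n_mutated_samples: int
    observed_smds: float
    exceed_count: int
    trials: int
    p_value: float
    p_value_add_one: float
    tested: bool
    rng_seed: tuple[int, ...] | None = None
    null_smds: np.ndarray | None = None


def compute_mds(assignment: GeneAssignment, scores: ScoreSet) -> MdsMatrix:
    """Per-(gene, sample) maximum variant score; 0.0 for samples with no SNVs."""
    mds = MdsMatrix(score_name=scores.name)
    for gene_id, per_sample in assignment.by_gene.items():
        for sample_id, snvs in per_sample.items():
            if not snvs:
                continue
            mds.values[(gene_id, sample_id)] = max(
                scores.score(*snv.key) for snv in snvs
            )
    return mds


def compute_smds(mds: MdsMatrix, gene_id: str, sample_ids: Iterable[str]) -> float:
    """Sum of per-sample MDS over the cohort for one gene."""
    return float(sum(mds.get(gene_id, s) for s in sample_ids))


def permute_sample_snvs(
    gene: GeneRegion,
    index: TrinucleotideIndex,
    snvs: Sequence[SNV],
    rng: np.random.Generator,
) -> PermutedPlacement:
    """Relocate one sample's SNVs, preserving each reference trinucleotide.

    Each SNV draws a uniform position from its own trinucleotide bucket
    (which contains its original site), independently of the others.  An
    SNV whose window contains N has no bucket; it keeps its position with
    a logged warning.
    """
    moves: list[tuple[SNV, int]] = []
    sample_id = snvs[0].sample_id if snvs else ""
    for snv in snvs:
        tri = gene.trinucleotide_at(snv.pos)
        bucket = index.bucket(tri)
        if len(bucket) == 0:
            logger.warning(
                "%s:%d (%s) window %r contains N; SNV keeps its position",
                snv.chrom,
                snv.pos,
                gene.gene_id,
                tri,
            )
            moves.append((snv, snv.pos))
            continue
        new_pos = int(bucket[rng.integers(0, len(bucket))])
        moves.append((snv, new_pos))
    return PermutedPlacement(gene_id=gene.gene_id, sample_id=sample_id, moves=moves)


def _bucket_scores(
    gene: GeneRegion,
    index: TrinucleotideIndex,
    scores: ScoreSet,
    snv: SNV,
    cache: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """Bucket positions for an SNV's context plus their scores under its
    ref>alt substitution (cached per (trinucleotide, alt))."""
    tri = gene.trinucleotide_at(snv.pos)
    key = (tri, snv.alt)
    if key not in cache:
        bucket = index.bucket(tri)
        if len(bucket) == 0:  # N window: SNV is frozen at its own site
            bucket = np.array([snv.pos], dtype=np.int64)
        cache[key] = (bucket, scores.scores_at(gene.chrom, bucket, snv.ref, snv.alt))
    return cache[key]


def null_distribution(
    gene: GeneRegion,
    index: TrinucleotideIndex,
    sample_snvs: Mapping[str, Sequence[SNV]],
    scores: ScoreSet,
    trials: int = DEFAULT_TRIALS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo null vector of the gene statistic over ``trials`` trials.

    Every trial relocates every sample's SNVs (independent uniform draws
    within trinucleotide buckets), rescores the relocated variants and
    recomputes sum-over-samples of the per-sample maximum.
    """
    if rng is None:
        rng = np.random.default_rng()
    total = np.zeros(trials)
    cache: dict = {}
    for _, snvs in sorted(sample_snvs.items()):
        if not snvs:
            continue
        per_snv = np.empty((len(snvs), trials))
        for i, snv in enumerate(snvs):
            bucket, bucket_scores = _bucket_scores(gene, index, scores, snv, cache)
            draws = rng.integers(0, len(bucket), size=trials)
            per_snv[i] = bucket_scores[draws]
        total += per_snv.max(axis=0)
    return total


def empirical_pvalue(observed: float, null: np.ndarray) -> float:
    """Fraction of null values >= observed; may be exactly 0 or 1."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empirical_pvalue needs a non-empty null vector")
    return float(np.count_nonzero(null >= observed) / null.size)


def _stream_seed(global_seed: int, gene_id: str, score_name: str) -> tuple[int, ...]:
    """Deterministic per-(gene, score) RNG key, independent of run order."""
    return (
        int(global_seed) % (2**31),
        zlib.crc32(gene_id.encode()),
        zlib.crc32(score_name.encode()),
    )


def run_single_gene_test(
    gene: GeneRegion,
    index: TrinucleotideIndex,
    sample_snvs: Mapping[str, Sequence[SNV]],
    scores: ScoreSet,
    trials: int,
    global_seed: int,
    keep_null: bool = False,
) -> GeneTestResult:
    """Observed statistic, permutation null and empirical p for one gene."""
    n_snvs = sum(len(v) for v in sample_snvs.values())
    n_mutated = sum(1 for v in sample_snvs.values() if v)
    seed_key = _stream_seed(global_seed, gene.gene_id, scores.name)
    if n_snvs == 0:
        return GeneTestResult(
            gene_id=gene.gene_id,
            gene_name=gene.gene_name,
            score_name=scores.name,
            n_snvs=0,
            n_mutated_samples=0,
            observed_smds=0.0,
            exceed_count=trials,
            trials=trials,
            p_value=1.0,
            p_value_add_one=1.0,
            tested=False,
            rng_seed=seed_key,
        )
    observed = float(
        sum(
            max(scores.score(*snv.key) for snv in snvs)
            for snvs in sample_snvs.values()
            if snvs
        )
    )
    rng = np.random.default_rng(seed_key)
    null = null_distribution(gene, index, sample_snvs, scores, trials=trials, rng=rng)
    exceed = int(np.count_nonzero(null >= observed))
    return GeneTestResult(
        gene_id=gene.gene_id,
        gene_name=gene.gene_name,
        score_name=scores.name,
        n_snvs=n_snvs,
        n_mutated_samples=n_mutated,
        observed_smds=observed,
        exceed_count=exceed,
        trials=trials,
        p_value=exceed / trials,
        p_value_add_one=(exceed + 1) / (trials + 1),
        tested=True,
        rng_seed=seed_key,
        null_smds=null if keep_null else None,
    )


def run_gene_tests(
    regions: Sequence[GeneRegion],
    assignment: GeneAssignment,
    score_sets: Sequence[ScoreSet],
    trials: int = DEFAULT_TRIALS,
    global_seed: int = 0,
    n_jobs: int = 1,
    keep_null: bool = False,
    indexes: Mapping[str, TrinucleotideIndex] | None = None,
) -> list[GeneTestResult]:
    """Permutation test for every (gene, score set) pair.

    Each pair uses an RNG stream derived from (global_seed, gene_id,
    score_name), so results are bitwise reproducible and independent of
    execution order and of ``n_jobs``.  Genes with no SNVs are returned
    flagged untested with p = 1.
    """
    if indexes is None:
        indexes = {r.gene_id: index_trinucleotides(r) for r in regions}
    jobs = [
        (region, score_set)
        for region in regions
        for score_set in score_sets
    ]

    def _run(region: GeneRegion, score_set: ScoreSet) -> GeneTestResult:
        return run_single_gene_test(
            region,
            indexes[region.gene_id],
            assignment.samples_of(region.gene_id),
            score_set,
            trials=trials,
            global_seed=global_seed,
            keep_null=keep_null,
        )

    if n_jobs == 1:
        return [_run(region, score_set) for region, score_set in jobs]
    results = Parallel(n_jobs=n_jobs, prefer="threads")(
        delayed(_run)(region, score_set) for region, score_set in jobs
    )
    return list(results)
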