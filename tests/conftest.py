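"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pytest

from smds import (
    SNV,
    GeneRegion,
    ScoreSet,
    index_trinucleotides,
)


def brute_force_trinucleotide_scan(region: GeneRegion) -> dict[str, list[int]]:
    """Independent sliding-window oracle for the trinucleotide index."""
    buckets: dict[str, list[int]] = {}
    for pos in range(region.start, region.end + 1):
        i = pos - region.start + 1
        window = region.sequence[i - 1 : i + 2]
        if set(window) <= set("ACGT"):
            buckets.setdefault(window, []).append(pos)
    return buckets


def make_region(seq: str, chrom: str = "c", start: int = 2) -> GeneRegion:
    """Region whose margin-padded sequence is ``seq`` (in-region = seq[1:-1])."""
    end = start + len(seq) - 3
    return GeneRegion(
        gene_id="g", gene_name="g", chrom=chrom, start=start, end=end,
        strand="+", sequence=seq,
    )


def random_region(rng: np.random.Generator, length: int, with_n: bool = False) -> GeneRegion:
    alphabet = list("ACGTN" if with_n else "ACGT")
    p = [0.22, 0.22, 0.22, 0.22, 0.12] if with_n else None
    seq = "".join(rng.choice(alphabet, size=length + 2, p=p))
    return make_region(seq)


def exact_null_distribution(
    region: GeneRegion,
    sample_snvs: Mapping[str, Sequence[SNV]],
    scores: ScoreSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate the exact null of the gene statistic over all joint placements.

    Returns (values, probabilities); placements are independent uniform
    draws over each SNV's trinucleotide bucket, matching the engine's
    product-measure convention.  Only feasible for small buckets.
    """
    index = index_trinucleotides(region)
    flat: list[tuple[str, SNV, np.ndarray]] = []
    for sample_id, snvs in sorted(sample_snvs.items()):
        for snv in snvs:
            bucket = index.bucket(region.trinucleotide_at(snv.pos))
            if len(bucket) == 0:
                bucket = np.array([snv.pos])
            flat.append((sample_id, snv, bucket))
    values, probs = [], []
    sizes = [len(b) for _, _, b in flat]
    total = int(np.prod(sizes))
    for combo in itertools.product(*[range(n) for n in sizes]):
        per_sample: dict[str, float] = {}
        for (sample_id, snv, bucket), j in zip(flat, combo):
            s = scores.score(region.chrom, int(bucket[j]), snv.ref, snv.alt)
            per_sample[sample_id] = max(per_sample.get(sample_id, 0.0), s)
        values.append(sum(per_sample.values()))
        probs.append(1.0 / total)
    return np.asarray(values), np.asarray(probs)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small deterministic synthetic cohort exercising all pipeline stages."""
    from smds import CohortSpec, simulate_cohort

    spec = CohortSpec(
        n_genes=8,
        n_driver_genes=2,
        n_samples=12,
        gene_length=(400, 800),
        flank=300,
        seed=11,
    )
    return simulate_cohort(spec)
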