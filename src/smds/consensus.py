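"""Candidate selection, cross-model agreement, truth-set overlap and ranking.

Running the permutation test once per scoring system yields one candidate
gene list per model (genes with empirical p <= alpha, 0.01 by default).
This module quantifies how the models agree: exact-subset intersection
counts (UpSet-style), the per-model *consensus* (fraction of a model's
candidates also selected by at least two other models), overlap with a
curated truth set such as the Cancer Gene Census, and a combined
average-rank ordering of the models.  It also prepares QQ-plot tables with
pointwise order-statistic confidence bands for p-value calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta, rankdata

from .permutation import GeneTestResult

DEFAULT_ALPHA = 0.01


@dataclass
class CandidateSet:
    """Genes one model calls significant at its inclusive p-value cutoff."""

    score_name: str
    genes: frozenset[str]
    alpha: float = DEFAULT_ALPHA

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class IntersectionTable:
    """Exact-subset decomposition of the union of candidate sets.

    ``exact_counts`` maps each non-empty combination of model names to the
    number of genes selected by exactly that combination; the counts sum to
    the union size.  ``by_k`` aggregates genes selected by exactly k models.
    """

    model_names: list[str]
    exact_counts: dict[frozenset[str], int]
    gene_models: dict[str, frozenset[str]]

    @property
    def union_size(self) -> int:
        return len(self.gene_models)

    @property
    def by_k(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for models in self.gene_models.values():
            counts[len(models)] = counts.get(len(models), 0) + 1
        return dict(sorted(counts.items()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "models": "+".join(sorted(models)),
                "n_models": len(models),
                "n_genes": count,
            }
            for models, count in self.exact_counts.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["n_genes", "models"], ascending=[False, True])
            .reset_index(drop=True)
        )


@dataclass
class ModelEvaluation:
    """Per-model performance summary (candidate count, truth overlap, consensus)."""

    score_name: str
    n_significant: int
    cgc_overlap: float | None = None
    consensus: float | None = None
    cgc_rank: float | None = None
    consensus_rank: float | None = None
    average_rank: float | None = None


@dataclass
class QQData:
    """Sorted observed p-values vs uniform quantiles with a 95% band."""

    score_name: str
    observed: np.ndarray  # ascending
    expected: np.ndarray  # i / (n + 1)
    band_low: np.ndarray
    band_high: np.ndarray
    neg_log10_observed: np.ndarray
    neg_log10_expected: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "expected_p": self.expected,
                "observed_p": self.observed,
                "band_low": self.band_low,
                "band_high": self.band_high,
                "neg_log10_expected": self.neg_log10_expected,
                "neg_log10_observed": self.neg_log10_observed,
            }
        )


def select_candidates(
    results: Iterable[GeneTestResult], alpha: float = DEFAULT_ALPHA
) -> CandidateSet:
    """Candidate driver genes: tested genes with p <= alpha (inclusive)."""
    results = list(results)
    names = {r.score_name for r in results}
    if len(names) > 1:
        raise ValueError(f"results mix score sets: {sorted(names)}")
    score_name = names.pop() if names else ""
    genes = frozenset(
        r.gene_id for r in results if r.tested and r.p_value <= alpha
    )
    return CandidateSet(score_name=score_name, genes=genes, alpha=alpha)


def intersect_models(candidate_sets: Sequence[CandidateSet]) -> IntersectionTable:
    """Exact-subset intersection counts over >= 2 candidate sets."""
    if len(candidate_sets) < 2:
        raise ValueError("intersect_models needs at least two candidate sets")
    names = [cs.score_name for cs in candidate_sets]
    gene_models: dict[str, set[str]] = {}
    for cs in candidate_sets:
        for gene in cs.genes:
            gene_models.setdefault(gene, set()).add(cs.score_name)
    frozen = {g: frozenset(m) for g, m in gene_models.items()}
    exact: dict[frozenset[str], int] = {}
    for models in frozen.values():
        exact[models] = exact.get(models, 0) + 1
    return IntersectionTable(model_names=names, exact_counts=exact, gene_models=frozen)


def model_consensus(
    candidate_sets: Sequence[CandidateSet],
    min_other_models: int = 2,
    include_self: bool = False,
) -> dict[str, float]:
    """Fraction of each model's candidates selected by >= 2 *other* models.

    With ``include_self`` the count includes the model itself (sensitivity
    variant); the default excludes it.  Empty candidate sets get NaN.
    """
    if len(candidate_sets) < 3:
        raise ValueError("model consensus needs at least three candidate sets")
    membership: dict[str, set[str]] = {}
    for cs in candidate_sets:
        for gene in cs.genes:
            membership.setdefault(gene, set()).add(cs.score_name)
    out: dict[str, float] = {}
    for cs in candidate_sets:
        if not cs.genes:
            out[cs.score_name] = float("nan")
            continue
        n_shared = 0
        for gene in cs.genes:
            others = membership[gene] if include_self else membership[gene] - {cs.score_name}
            if len(others) >= min_other_models:
                n_shared += 1
        out[cs.score_name] = n_shared / len(cs.genes)
    return out


def truthset_overlap(candidate_set: CandidateSet, truth_genes: Iterable[str]) -> float:
    """Fraction of the truth set recovered: |candidates ∩ truth| / |truth|.

    Gene symbols are matched case-insensitively, no alias resolution.
    """
    truth = {g.strip().upper() for g in truth_genes if g.strip()}
    if not truth:
        raise ValueError("truth set is empty")
    candidates = {g.upper() for g in candidate_set.genes}
    return len(candidates & truth) / len(truth)


def rank_models(evaluations: Sequence[ModelEvaluation]) -> list[ModelEvaluation]:
    """Combined ranking on truth-set overlap and consensus (average ranks).

    Each criterion ranks models descending (best = 1) with average ranks on
    ties; the final order is ascending on the mean of the two ranks.
    """
    if len(evaluations) < 2:
        raise ValueError("rank_models needs at least two models")
    cgc = np.array([e.cgc_overlap for e in evaluations], dtype=float)
    cons = np.array([e.consensus for e in evaluations], dtype=float)
    cgc_ranks = rankdata(-cgc, method="average")
    cons_ranks = rankdata(-cons, method="average")
    ranked = []
    for e, cr, sr in zip(evaluations, cgc_ranks, cons_ranks):
        ranked.append(
            ModelEvaluation(
                score_name=e.score_name,
                n_significant=e.n_significant,
                cgc_overlap=e.cgc_overlap,
                consensus=e.consensus,
                cgc_rank=float(cr),
                consensus_rank=float(sr),
                average_rank=float((cr + sr) / 2.0),
            )
        )
    return sorted(ranked, key=lambda e: (e.average_rank, e.score_name))


def evaluate_models(
    candidate_sets: Sequence[CandidateSet],
    truth_genes: Iterable[str] | None = None,
) -> list[ModelEvaluation]:
    """Assemble per-model evaluations (count, truth overlap, consensus) and rank."""
    truth = list(truth_genes) if truth_genes is not None else None
    consensus = (
        model_consensus(candidate_sets) if len(candidate_sets) >= 3 else {}
    )
    evals = []
    for cs in candidate_sets:
        evals.append(
            ModelEvaluation(
                score_name=cs.score_name,
                n_significant=len(cs),
                cgc_overlap=truthset_overlap(cs, truth) if truth else None,
                consensus=consensus.get(cs.score_name),
            )
        )
    if truth and consensus:
        return rank_models(evals)
    return evals


def evaluations_to_frame(evaluations: Sequence[ModelEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": [e.score_name for e in evaluations],
            "n_significant": [e.n_significant for e in evaluations],
            "cgc_overlap": [e.cgc_overlap for e in evaluations],
            "consensus": [e.consensus for e in evaluations],
            "cgc_rank": [e.cgc_rank for e in evaluations],
            "consensus_rank": [e.consensus_rank for e in evaluations],
            "average_rank": [e.average_rank for e in evaluations],
        }
    )


def qq_data(
    p_values: Sequence[float],
    score_name: str = "",
    band: float = 0.95,
    p_values_for_log: Sequence[float] | None = None,
) -> QQData:
    """QQ-plot table for observed p-values against Uniform(0, 1).

    The i-th order statistic is paired with the plotting position
    i / (n + 1); the pointwise band comes from the Beta(i, n - i + 1)
    distribution of uniform order statistics at (1 - band)/2 and
    1 - (1 - band)/2.  The -log10 columns use ``p_values_for_log`` when
    given (e.g. add-one-corrected p-values that avoid log(0)), sorted
    alongside the primary p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("qq_data needs at least one p-value")
    order = np.argsort(p, kind="stable")
    observed = p[order]
    n = p.size
    i = np.arange(1, n + 1)
    expected = i / (n + 1.0)
    lo = (1.0 - band) / 2.0
    band_low = beta.ppf(lo, i, n - i + 1)
    band_high = beta.ppf(1.0 - lo, i, n - i + 1)
    if p_values_for_log is not None:
        plog = np.asarray(p_values_for_log, dtype=float)[order]
    else:
        plog = observed
    with np.errstate(divide="ignore"):
        neg_obs = -np.log10(plog)
    return QQData(
        score_name=score_name,
        observed=observed,
        expected=expected,
        band_low=band_low,
        band_high=band_high,
        neg_log10_observed=neg_obs,
        neg_log10_expected=-np.log10(expected),
    )
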