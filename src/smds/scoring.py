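"""Uniform [0,1] deleteriousness scores and cross-score comparison.

Scoring systems differ wildly in their raw scales (phred-like, probabilities,
delta-PSI).  To make them comparable, a score set can be rank-rescaled to
[0, 1] over the raw values observed on the cohort's SNVs (empirical-CDF /
average-rank transform).  Variants absent from a score table — e.g. a
non-missense SNV under a missense-only predictor — receive the lowest
score, 0.0.

The comparison layer reports pairwise Pearson correlation between score
sets evaluated on the same variants, the derived distance 1 - r, and a
UPGMA dendrogram over that distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]

#: Pearson-r bands used when reporting pairwise score agreement
CORRELATION_BANDS = (("low", 0.4), ("medium", 0.7), ("high", np.inf))


def classify_correlation(r: float) -> str:
    """Band a Pearson r: low (r <= 0.4), medium (0.4 < r < 0.7), high (r >= 0.7)."""
    if np.isnan(r):
        return "undefined"
    if r <= 0.4:
        return "low"
    if r < 0.7:
        return "medium"
    return "high"


def rescale_rank(raw_scores: Sequence[float]) -> "RankRescaler":
    """Fit the rank transform mapping observed raws to [0, 1].

    Average ranks are used for ties; the minimum observed raw maps to 0,
    the maximum to 1, and intermediate values to (rank - 1) / (n - 1),
    which is invariant under any strictly monotone transform of the raws.
    Unseen raws are mapped by linear interpolation between observed ones
    (clipped at the extremes).
    """
    raws = np.asarray(raw_scores, dtype=float)
    if raws.size < 1:
        raise ValueError("rescale_rank needs at least one raw score")
    if np.unique(raws).size == 1:
        logger.warning(
            "all %d raw scores identical (%g); rank rescaling maps them to 0.5",
            raws.size,
            raws[0],
        )
        return RankRescaler(knots=np.array([raws[0]]), values=np.array([0.5]))
    ranks = rankdata(raws, method="average")
    scaled = (ranks - 1.0) / (raws.size - 1.0)
    # one knot per distinct raw (ties share a single average-rank value)
    knots, first_idx = np.unique(raws, return_index=True)
    return RankRescaler(knots=knots, values=scaled[first_idx])


@dataclass
class RankRescaler:
    """Monotone raw -> [0,1] map frozen from one raw-score collection."""

    knots: np.ndarray
    values: np.ndarray

    def __call__(self, raw):
        return np.interp(raw, self.knots, self.values)


@dataclass
class ScoreSet:
    """A named scoring system mapping (chrom, pos, ref, alt) -> [0, 1].

    ``lookup`` is either a mapping keyed by the variant tuple or a callable
    returning the raw score (or None when the variant is unscored).  With
    ``rescale_mode="rank"`` the raw values are passed through a rank
    transform fitted once (see :func:`rescale_rank`); the same frozen map
    scores both observed and permuted variants.  Missing variants always
    score ``missing_value`` (0.0).

    ``position_only`` supports splicing-style tables keyed by (chrom, pos)
    regardless of the substitution.
    """

    name: str
    lookup: Mapping[VariantKey, float] | Callable[[str, int, str, str], float | None]
    rescale_mode: str = "none"  # {"none", "rank"}
    position_only: bool = False
    missing_value: float = 0.0
    _rescaler: RankRescaler | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.rescale_mode not in ("none", "rank"):
            raise ValueError(f"unknown rescale_mode {self.rescale_mode!r}")

    def raw(self, chrom: str, pos: int, ref: str, alt: str) -> float | None:
        if callable(self.lookup):
            return self.lookup(chrom, pos, ref, alt)
        key = (chrom, pos) if self.position_only else (chrom, pos, ref, alt)
        return self.lookup.get(key)

    def fit_rescaler(self, variants: Sequence[VariantKey]) -> None:
        """Freeze the rank transform on the raws of the given cohort variants."""
        if self.rescale_mode != "rank":
            return
        raws = [self.raw(*v) for v in variants]
        raws = [r for r in raws if r is not None]
        if not raws:
            raise ValueError(
                f"score set {self.name!r}: no scored variants to fit rescaling on"
            )
        self._rescaler = rescale_rank(raws)

    def score(self, chrom: str, pos: int, ref: str, alt: str) -> float:
        raw = self.raw(chrom, pos, ref, alt)
        if raw is None:
            return self.missing_value
        if self.rescale_mode == "rank":
            if self._rescaler is None:
                raise RuntimeError(
                    f"score set {self.name!r} uses rank rescaling but "
                    "fit_rescaler() has not been called"
                )
            raw = float(self._rescaler(raw))
        return float(min(1.0, max(0.0, raw)))

    def scores_at(
        self, chrom: str, positions: np.ndarray, ref: str, alt: str
    ) -> np.ndarray:
        """Vectorised score lookup over many positions of one substitution."""
        return np.array(
            [self.score(chrom, int(p), ref, alt) for p in positions], dtype=float
        )


def score_variant(scores: ScoreSet, chrom: str, pos: int, ref: str, alt: str) -> float:
    """Rescaled score of one variant; 0.0 when the table does not cover it."""
    return scores.score(chrom, pos, ref, alt)


@dataclass
class ScoreComparison:
    """Pairwise Pearson correlation between score sets and the 1 - r distance."""

    names: list[str]
    correlation: np.ndarray  # K x K, unit diagonal, NaN where undefined
    linkage_matrix: np.ndarray | None = None

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.correlation

    def band_table(self) -> list[tuple[str, str, float, str]]:
        rows = []
        for i in range(len(self.names)):
            for j in range(i + 1, len(self.names)):
                r = float(self.correlation[i, j])
                rows.append((self.names[i], self.names[j], r, classify_correlation(r)))
        return rows


def correlation_matrix(score_vectors: Mapping[str, Sequence[float]]) -> ScoreComparison:
    """Pearson correlation between score sets over a common variant list.

    Vectors must be equal length >= 3.  A zero-variance vector yields NaN
    (undefined) correlations for its pairs, reported rather than raised.
    """
    names = list(score_vectors)
    mat = np.asarray([score_vectors[n] for n in names], dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 3:
        raise ValueError("correlation_matrix needs equal-length vectors of length >= 3")
    corr = np.ones((len(names), len(names)))
    sd = mat.std(axis=1)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if sd[i] == 0 or sd[j] == 0:
                corr[i, j] = corr[j, i] = np.nan
            else:
                corr[i, j] = corr[j, i] = np.corrcoef(mat[i], mat[j])[0, 1]
    return ScoreComparison(names=names, correlation=corr)


def upgma_cluster(distances: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, str]:
    """UPGMA (average-linkage) agglomeration of a symmetric distance matrix.

    Returns the SciPy linkage matrix (merge heights in column 2 are
    cophenetic distances; the ultrametric node height is half that) and a
    Newick serialisation with branch lengths on the half-distance scale.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T) or not np.allclose(
        np.diag(distances), 0.0
    ):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    Z = linkage(squareform(distances, checks=False), method="average")
    return Z, linkage_to_newick(Z, names)


def linkage_to_newick(Z: np.ndarray, names: Sequence[str]) -> str:
    """Newick string from a linkage matrix; node heights = distance / 2."""
    n = len(names)

    def height(node: int) -> float:
        return 0.0 if node < n else Z[node - n, 2] / 2.0

    def render(node: int) -> str:
        if node < n:
            return str(names[node])
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return (
            f"({render(a)}:{h - height(a):.6g},{render(b)}:{h - height(b):.6g})"
        )

    return render(2 * n - 2) + ";"
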