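# Methods

## Model

The test asks, gene by gene, whether a cohort's somatic SNVs are more
deleterious than expected given (i) each sample's mutation count in the
gene and (ii) the gene's sequence composition. Its assumptions:

- passenger SNVs are exchangeable among in-gene positions that share a
  reference trinucleotide (mutability is driven by local context);
- one sufficiently deleterious mutation per sample is what matters, so
  each sample contributes only its maximum score (MDS) — recurrent
  low-scoring mutations in one sample do not accumulate;
- samples are independent, so per-sample maxima add (SMDS);
- only a fraction of samples need carry a driver mutation for the gene
  sum to shift detectably.

The null relocates every observed SNV independently and uniformly within
its trinucleotide bucket (the set of in-region positions whose centred
forward-strand 3-mer matches), keeps its ref&gt;alt substitution,
rescores by table lookup and recomputes the statistic. Relocation is
with replacement: two SNVs may land on one site, and an SNV may return
to its own site. This makes the null a product measure — exactly
enumerable for small genes, which the test suite exploits — at the cost
of admitting collisions the cohort data cannot show; at realistic
mutation densities collisions are rare and their effect on the gene sum
is bounded by one sample's maximum.

Trinucleotide context is matched literally on the forward strand (192
mutation classes), with no pyrimidine-centred collapsing: collapsing
would let an SNV jump to the opposite strand's context and change the
null. A 96-class signature is still accepted by the simulator and
expanded symmetrically.

## Coordinates, regions, scores

Everything is 1-based inclusive (VCF convention); BED input is converted
on read. A gene's tested region is its canonical transcript's genomic
span extended `flank` bases both sides (default 5000), clipped at
chromosome ends; the stored sequence carries one extra base per side so
every in-region position has a full 3-mer, with N-padding at chromosome
edges. Positions whose window contains N join no bucket and are frozen
in place if mutated. An SNV inside several overlapping gene regions
enters every one of them — tests are per-gene and independent.

Scores are per-variant values in [0, 1]; systems on other scales
(phred-like, ΔPSI) are rank-rescaled: the empirical CDF of the raw
scores observed on the cohort's SNVs, average ranks for ties, min → 0,
max → 1, linear interpolation between observed raws. The map is frozen
once and reused for permuted variants, so observed and simulated SNVs
are scored identically. Rescaling on the cohort's own variants (rather
than a genome-wide precomputed distribution) keeps the package
self-contained; the fit set is caller-controlled via
`ScoreSet.fit_rescaler`. Variants absent from a table score 0.0 — the
convention that makes missense-only or splicing-only systems usable
genome-wide, at the price of diluting their gene sums.

## Randomness and determinism

Each (gene, scoring system) pair gets its own RNG stream seeded by
(global seed mod 2³¹, CRC-32 of the gene id, CRC-32 of the score name),
so results are bitwise reproducible and independent of gene order and of
the joblib thread count. The p-value is exceed_count/m exactly (p = 0 is
reportable); an add-one-corrected (count+1)/(m+1) companion value is
emitted for log-scale QQ plotting only, never for selection.

## Evaluation layer

Candidates are tested genes with p ≤ α (inclusive; α = 0.01 default).
Consensus for model M is the fraction of M's candidates selected by at
least two models other than M (an include-self variant exists behind a
flag). Truth-set overlap is |candidates ∩ truth| / |truth| with
case-insensitive symbol matching and no alias resolution. Models are
ranked descending on truth overlap and on consensus with average ranks
for ties, then ordered by the mean of the two ranks; average-rank is the
documented tie rule. QQ tables pair the i-th order statistic with
i/(n+1) and a pointwise 95% band from Beta(i, n−i+1) quantiles.

Pairwise score agreement is Pearson r on a common variant list
(bands: low r ≤ 0.4, medium, high r ≥ 0.7), with UPGMA (SciPy average
linkage) on 1 − r; dendrogram node heights are half the cophenetic
distance, serialised as Newick.

## Synthetic cohorts

The simulator emulates a somatic cohort at desk scale: each gene on its
own contig (GC content 0.45), passenger SNV counts per (sample, gene)
Poisson with mean 1.0 over the region, contexts drawn from a mutation
signature — by default mildly transition-skewed, C&gt;T/G&gt;A classes
at 3× weight — and positions uniform within the matching bucket. If a
drawn class has no site in a gene the signature is renormalised over the
classes present (with ≥ 1 kb regions every context is essentially always
present, so class frequencies are preserved; verified by goodness-of-fit
in the tests). Driver genes get one designated site each, mutated with
the same substitution in a carrier fraction of samples (default 0.4 of
50 samples; one driver mutation per carrier). Scoring systems are keyed
hash functions: driver-site variants draw from [0.9, 1.0], everything
else from [0, 0.3] by default, optionally with a missingness fraction
emulating missense-only coverage; writing the cohort to disk enumerates
the same function into plain TSV, so file-based and in-memory runs
agree exactly. Default gene lengths are 1–3 kb with a 1 kb simulation
flank — compact enough to test quickly, long enough that every
trinucleotide bucket is well populated.

What the simulator does not model: chromatin- or replication-timing
covariates of mutation rate, indels, copy number, subclonality,
sample-specific signature mixtures, and correlated scores between
systems (beyond shared driver sites). Passing tests therefore show the
statistic and its null are implemented correctly and calibrated under
context-exchangeability — not that the method overcomes covariate
structure in real tumours that context alone cannot capture.

## Problem sizes used in the checks

Calibration uses 200 driver-free genes (0.6–1.2 kb, 300 bp flank) × 30
samples at m = 1000 with i.i.d. uniform scores; driver recovery uses the
default cohort (50 genes, 10 drivers, 50 samples) at m = 1000 and a
carrier-fraction grid (0.02, 0.2, 0.5) at m = 400; oracle-equivalence
checks enumerate genes with ≤ 3 SNVs exhaustively. These sizes give
stable statistics while keeping the whole suite fast.

## Known limitations and numerical notes

- The permutation preserves counts and context but not inter-mutation
  spacing; clustered hypermutation (kataegis) is treated as independent
  draws.
- Raising an observed SNV's score never lowers the observed SMDS, but it
  can *raise* the exact p-value: the raise also lifts null draws that
  re-land on the same site, and with the tie-inclusive ≥ rule a sample
  whose null contribution collapses onto its observed value converts
  former misses into ties. Significance is therefore not guaranteed to
  be monotone in single-variant score edits.
- All-identical raw scores rank-rescale to 0.5 (with a warning); a
  zero-variance score vector yields undefined (NaN) correlations,
  reported rather than raised.
- Ties in rescaling use average ranks; UPGMA inherits SciPy's
  tie-breaking on equal merge distances; candidate sets are order-free
  (frozensets), and every output table has a deterministic sort.
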