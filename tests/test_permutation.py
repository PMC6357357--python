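"""MDS/SMDS statistics, the permutation null, and empirical p-values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smds import (
    SNV,
    ScoreSet,
    assign_snvs,
    compute_mds,
    compute_smds,
    empirical_pvalue,
    index_trinucleotides,
    null_distribution,
    permute_sample_snvs,
    run_gene_tests,
)
from smds.permutation import run_single_gene_test

from conftest import exact_null_distribution, make_region, random_region


def _score_table(region, fn):
    """Dense score table over all in-region substitutions via ``fn(pos, alt)``."""
    table = {}
    for pos in range(region.start, region.end + 1):
        ref = region.base_at(pos)
        if ref == "N":
            continue
        for alt in "ACGT":
            if alt != ref:
                table[(region.chrom, pos, ref, alt)] = fn(pos, alt)
    return table


class TestMdsSmds:
    def test_mds_is_the_maximum_score(self):
        region = make_region("A" * 12)
        scores = {("c", 3, "A", "G"): 0.2, ("c", 4, "A", "G"): 0.9, ("c", 5, "A", "G"): 0.5}
        snvs = [SNV("c", p, "A", "G", "S1") for p in (3, 4, 5)]
        assignment = assign_snvs(snvs, [region])
        mds = compute_mds(assignment, ScoreSet("s", scores))
        assert mds.get("g", "S1") == 0.9

    def test_sample_without_snvs_has_zero_mds(self):
        region = make_region("A" * 12)
        assignment = assign_snvs([SNV("c", 3, "A", "G", "S1")], [region])
        mds = compute_mds(assignment, ScoreSet("s", {("c", 3, "A", "G"): 0.4}))
        assert mds.get("g", "S2") == 0.0

    def test_all_snvs_unscored_gives_zero_mds(self):
        # missense-only style table that covers none of the sample's SNVs
        region = make_region("A" * 12)
        assignment = assign_snvs([SNV("c", 3, "A", "G", "S1")], [region])
        mds = compute_mds(assignment, ScoreSet("missense", {}))
        assert mds.get("g", "S1") == 0.0

    def test_smds_sums_over_all_samples(self):
        region = make_region("A" * 12)
        scores = {("c", 3, "A", "G"): 0.9, ("c", 4, "A", "G"): 0.7}
        snvs = [SNV("c", 3, "A", "G", "S1"), SNV("c", 4, "A", "G", "S3")]
        mds = compute_mds(assign_snvs(snvs, [region]), ScoreSet("s", scores))
        assert compute_smds(mds, "g", ["S1", "S2", "S3"]) == pytest.approx(1.6)

    def test_smds_zero_when_all_samples_zero(self):
        mds = compute_mds(
            assign_snvs([], [make_region("A" * 12)]), ScoreSet("s", {})
        )
        assert compute_smds(mds, "g", ["S1", "S2"]) == 0.0

    def test_one_perfect_mutation_per_sample_reaches_sample_count(self):
        region = make_region("A" * 12)
        snvs = [SNV("c", 3 + i, "A", "G", f"S{i}") for i in range(7)]
        table = {s.key: 1.0 for s in snvs}
        mds = compute_mds(assign_snvs(snvs, [region]), ScoreSet("s", table))
        assert compute_smds(mds, "g", [f"S{i}" for i in range(7)]) == 7.0


class TestEmpiricalPvalue:
    def test_counting_rule_with_ties_included(self):
        null = np.arange(1.0, 11.0)  # {1..10}
        assert empirical_pvalue(10.0, null) == pytest.approx(0.1)

    def test_observed_above_all_null_gives_zero(self):
        assert empirical_pvalue(11.0, np.arange(1.0, 11.0)) == 0.0

    def test_observed_at_or_below_all_null_gives_one(self):
        assert empirical_pvalue(1.0, np.arange(1.0, 11.0)) == 1.0
        assert empirical_pvalue(0.5, np.arange(1.0, 11.0)) == 1.0

    def test_empty_null_is_an_error(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, np.array([]))


class TestPermutePlacements:
    def test_unique_context_is_a_forced_placement(self):
        # single ACG in the region: its SNV can only stay put
        region = make_region("TACGTTTTT")
        index = index_trinucleotides(region)
        snv = SNV("c", 3, "C", "T", "S1")
        rng = np.random.default_rng(0)
        for _ in range(20):
            placement = permute_sample_snvs(region, index, [snv], rng)
            assert placement.moves == [(snv, 3)]

    def test_draws_are_uniform_over_the_bucket(self):
        # all-A region: every position is one AAA bucket of size 10
        region = make_region("A" * 12)
        index = index_trinucleotides(region)
        bucket = index.bucket("AAA")
        assert len(bucket) == 10
        snv = SNV("c", 5, "A", "G", "S1")
        rng = np.random.default_rng(1)
        n = 10_000
        counts = {int(p): 0 for p in bucket}
        for _ in range(n):
            (_, pos), = permute_sample_snvs(region, index, [snv], rng).moves
            counts[pos] += 1
        expected = n / len(bucket)
        # 5 sigma binomial tolerance per cell
        sigma = np.sqrt(n * 0.1 * 0.9)
        for c in counts.values():
            assert abs(c - expected) < 5 * sigma

    def test_every_placement_preserves_the_reference_trinucleotide(self):
        rng = np.random.default_rng(2)
        region = random_region(rng, 300, with_n=True)
        index = index_trinucleotides(region)
        eligible = sorted(int(p) for b in index.buckets.values() for p in b)
        snvs = []
        for i, pos in enumerate(rng.choice(eligible, size=12, replace=False)):
            ref = region.base_at(int(pos))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            snvs.append(SNV("c", int(pos), ref, alt, f"S{i % 3}"))
        for _ in range(200):
            placement = permute_sample_snvs(region, index, snvs, rng)
            assert len(placement.moves) == len(snvs)
            for snv, new_pos in placement.moves:
                assert region.trinucleotide_at(new_pos) == region.trinucleotide_at(snv.pos)


class TestNullDistribution:
    def test_position_independent_scores_freeze_the_statistic(self):
        region = make_region("A" * 22)
        index = index_trinucleotides(region)
        table = _score_table(region, lambda pos, alt: 0.6)
        scores = ScoreSet("s", table)
        sample_snvs = {
            "S1": [SNV("c", 4, "A", "G", "S1"), SNV("c", 9, "A", "T", "S1")],
            "S2": [SNV("c", 12, "A", "C", "S2")],
        }
        null = null_distribution(region, index, sample_snvs, scores, trials=300,
                                 rng=np.random.default_rng(0))
        assert np.all(null == pytest.approx(1.2))  # 2 mutated samples x 0.6

    def test_size_one_buckets_reproduce_the_observed_configuration(self):
        # every in-region 3-mer unique: permutation cannot move anything
        region = make_region("AACGTGCATT")
        index = index_trinucleotides(region)
        assert all(len(b) == 1 for b in index.buckets.values())
        rng = np.random.default_rng(5)
        snvs = {"S1": [SNV("c", 4, "G", "A", "S1")], "S2": [SNV("c", 6, "G", "C", "S2")]}
        table = _score_table(region, lambda pos, alt: (pos * 7 % 5) / 5.0)
        scores = ScoreSet("s", table)
        observed = sum(
            max(scores.score(*s.key) for s in g) for g in snvs.values()
        )
        null = null_distribution(region, index, snvs, scores, trials=100, rng=rng)
        assert np.all(null == pytest.approx(observed))

    def test_two_outcome_null_matches_exact_enumeration(self):
        # one sample, one SNV, bucket {p1, p2} scored {0.2, 1.0}
        region = make_region("TACGTACGTT")  # context ACG at positions 3 and 7 only
        index = index_trinucleotides(region)
        snv = SNV("c", 3, "C", "T", "S1")
        bucket = index.bucket(region.trinucleotide_at(3))
        assert list(bucket) == [3, 7]
        table = {("c", 3, "C", "T"): 0.2, ("c", 7, "C", "T"): 1.0}
        scores = ScoreSet("s", table)
        null = null_distribution(
            region, index, {"S1": [snv]}, scores, trials=1000,
            rng=np.random.default_rng(7),
        )
        assert set(np.round(np.unique(null), 6)) == {0.2, 1.0}
        exact_mean, exact_var = 0.6, 0.16
        se_mean = np.sqrt(exact_var / 1000)
        assert abs(null.mean() - exact_mean) < 3 * se_mean

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        region = make_region("".join(rng.choice(list("ACGT"), size=18)))
        index = index_trinucleotides(region)
        eligible = sorted(int(p) for b in index.buckets.values() for p in b)
        picks = rng.choice(eligible, size=3, replace=False)
        sample_snvs = {}
        for i, pos in enumerate(picks):
            ref = region.base_at(int(pos))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            sid = f"S{i % 2}"
            sample_snvs.setdefault(sid, []).append(SNV("c", int(pos), ref, alt, sid))
        scores = ScoreSet("s", _score_table(region, lambda pos, alt: ((pos * 13 + ord(alt)) % 17) / 16.0))
        values, probs = exact_null_distribution(region, sample_snvs, scores)
        m = 1000
        null = null_distribution(region, index, sample_snvs, scores, trials=m,
                                 rng=np.random.default_rng(13))
        exact_mean = float((values * probs).sum())
        exact_var = float((probs * (values - exact_mean) ** 2).sum())
        assert abs(null.mean() - exact_mean) < 3 * np.sqrt(exact_var / m) + 1e-12

    def test_raising_an_observed_score_cannot_decrease_the_statistic(self):
        region = make_region("A" * 12)
        snvs = [SNV("c", 3, "A", "G", "S1"), SNV("c", 7, "A", "T", "S2")]
        assignment = assign_snvs(snvs, [region])
        low = ScoreSet("s", {snvs[0].key: 0.3, snvs[1].key: 0.5})
        high = ScoreSet("s", {snvs[0].key: 0.8, snvs[1].key: 0.5})
        d_low = compute_smds(compute_mds(assignment, low), "g", ["S1", "S2"])
        d_high = compute_smds(compute_mds(assignment, high), "g", ["S1", "S2"])
        assert d_high >= d_low


class TestRunGeneTests:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        regions = [random_region(rng, 200) for _ in range(3)]
        for i, r in enumerate(regions):
            r.gene_id = r.gene_name = f"g{i}"
            r.chrom = f"g{i}"
        snvs = []
        for r in regions[:2]:  # third gene left unmutated
            index = index_trinucleotides(r)
            eligible = sorted(int(p) for b in index.buckets.values() for p in b)
            for i, pos in enumerate(rng.choice(eligible, size=6, replace=False)):
                ref = r.base_at(int(pos))
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                snvs.append(SNV(r.chrom, int(pos), ref, alt, f"S{i % 3}"))
        scores = ScoreSet("s", lambda c, p, ref, a: ((hash((c, p, a)) % 97) / 96.0))
        return regions, assign_snvs(snvs, regions), scores

    def test_same_seed_reproduces_identical_results(self):
        regions, assignment, scores = self._cohort()
        r1 = run_gene_tests(regions, assignment, [scores], trials=200, global_seed=42)
        r2 = run_gene_tests(regions, assignment, [scores], trials=200, global_seed=42)
        assert [(a.gene_id, a.observed_smds, a.p_value) for a in r1] == [
            (b.gene_id, b.observed_smds, b.p_value) for b in r2
        ]

    def test_results_do_not_depend_on_gene_order_or_parallelism(self):
        regions, assignment, scores = self._cohort()
        r1 = run_gene_tests(regions, assignment, [scores], trials=200, global_seed=7)
        r2 = run_gene_tests(
            regions[::-1], assignment, [scores], trials=200, global_seed=7, n_jobs=2
        )
        key = lambda rs: sorted((a.gene_id, a.observed_smds, a.p_value) for a in rs)
        assert key(r1) == key(r2)

    def test_gene_without_snvs_is_flagged_untested(self):
        regions, assignment, scores = self._cohort()
        results = {r.gene_id: r for r in run_gene_tests(
            regions, assignment, [scores], trials=100, global_seed=1
        )}
        assert results["g2"].tested is False
        assert results["g2"].p_value == 1.0
        assert results["g2"].observed_smds == 0.0

    def test_one_result_per_gene_score_pair(self):
        regions, assignment, _ = self._cohort()
        s1 = ScoreSet("one", lambda c, p, r, a: 0.5)
        s2 = ScoreSet("two", lambda c, p, r, a: 0.25)
        results = run_gene_tests(regions, assignment, [s1, s2], trials=50, global_seed=3)
        assert len(results) == len(regions) * 2
        assert {(r.gene_id, r.score_name) for r in results} == {
            (g.gene_id, s) for g in regions for s in ("one", "two")
        }


class TestSingleGeneTest:
    def test_pvalue_equals_exceed_count_over_trials(self):
        rng = np.random.default_rng(21)
        region = random_region(rng, 150)
        index = index_trinucleotides(region)
        eligible = sorted(int(p) for b in index.buckets.values() for p in b)
        pos = int(rng.choice(eligible))
        ref = region.base_at(pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snvs = {"S1": [SNV(region.chrom, pos, ref, alt, "S1")]}
        scores = ScoreSet("s", lambda c, p, r, a: (p % 11) / 10.0)
        result = run_single_gene_test(
            region, index, snvs, scores, trials=500, global_seed=9, keep_null=True
        )
        assert result.p_value == result.exceed_count / result.trials
        assert result.p_value == empirical_pvalue(result.observed_smds, result.null_smds)
        assert result.p_value_add_one == (result.exceed_count + 1) / (result.trials + 1)
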