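"""Distance-CDF enrichment, co-occupancy, pausing calls, rank-sum strata."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from cistrodyn.core import GeneModel, GenomicInterval, Peak, PeakSet
from cistrodyn.integration import (
    assign_strata,
    background_cdf,
    cdf_enrichment,
    classify_repression_mechanism,
    concordance_fraction,
    distance_cdf,
    DistanceCDF,
    gene_nearest_distances,
    occupancy_expression_correlation,
    rank_sum_test,
    stratified_ratio_test,
    stratify_by_cooccupancy,
)


def gene(gid, tss, chrom="chr1"):
    return GeneModel(gid, chrom, "+", (tss,) if isinstance(tss, int) else tuple(tss))


def ps(*ivs, chrom="chr1"):
    return PeakSet([Peak(GenomicInterval(chrom, a, b), 0) for a, b in ivs])


class TestDistanceCDF:
    def test_direct_counting_example(self):
        genes = [gene("a", 1000), gene("b", 2000), gene("c", 30_000)]
        sites = ps((1000, 1100), (1500, 1600), (50_000, 50_100))
        cdf = distance_cdf(genes, sites, [1_000, 10_000, 100_000])
        assert cdf.fractions == (2 / 3, 2 / 3, 1.0)

    def test_sites_on_every_tss(self):
        genes = [gene("a", 10), gene("b", 500)]
        sites = ps((0, 1000))
        cdf = distance_cdf(genes, sites, [10, 100])
        assert cdf.fractions == (1.0, 1.0)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            distance_cdf([], ps((0, 10)), [100])

    def test_site_free_chromosome_stays_in_denominator(self):
        genes = [gene("a", 100), gene("b", 100, chrom="chr2")]
        sites = ps((90, 120))
        cdf = distance_cdf(genes, sites, [1_000])
        assert cdf.fractions == (0.5,)

    def test_empty_site_set_gives_zero_fractions(self):
        cdf = background_cdf([gene("a", 5)], PeakSet([]), [100, 1000])
        assert cdf.fractions == (0.0, 0.0)

    def test_minimum_over_transcripts_and_bruteforce_oracle(self, rng):
        genes = [gene(f"g{i}", [int(t) for t in rng.integers(0, 100_000, rng.integers(1, 4))])
                 for i in range(40)]
        coords = [(int(s), int(s) + 50) for s in rng.integers(0, 100_000, 30)]
        sites = ps(*coords)
        d = gene_nearest_distances(genes, sites)
        for g, got in zip(genes, d):
            expect = min(
                0 if a <= t < b else (a - t if t < a else t - (b - 1))
                for t in g.tss for a, b in coords
            )
            assert got == expect

    def test_nondecreasing_invariant_enforced(self):
        with pytest.raises(ValueError):
            DistanceCDF("x", (1, 2), (0.5, 0.4), 10)


class TestCDFEnrichment:
    def test_identical_and_uniform_offset(self):
        a = DistanceCDF("t", (1, 2, 3), (0.2, 0.4, 0.6), 10)
        assert cdf_enrichment(a, a) == (0.0, 0.0)
        b = DistanceCDF("b", (1, 2, 3), (0.0, 0.2, 0.4), 10)
        gap, area = cdf_enrichment(a, b)
        assert gap == pytest.approx(0.2) and area == pytest.approx(0.2)

    def test_cutoff_mismatch_rejected(self):
        a = DistanceCDF("t", (1, 2), (0.1, 0.2), 5)
        b = DistanceCDF("b", (1, 3), (0.1, 0.2), 5)
        with pytest.raises(ValueError):
            cdf_enrichment(a, b)


class TestCooccupancy:
    def test_degenerate_partitions(self):
        sites = ps((0, 10), (20, 30))
        both, none = stratify_by_cooccupancy(sites, sites)
        assert len(both) == 2 and len(none) == 0
        w, wo = stratify_by_cooccupancy(sites, ps((100, 110)))
        assert len(w) == 0 and len(wo) == 2

    def test_partition_matches_all_pairs_oracle(self, rng):
        coords = [(int(s), int(s) + 20) for s in rng.integers(0, 3000, 25)]
        marks = [(int(s), int(s) + 20) for s in rng.integers(0, 3000, 15)]
        sites, mark = ps(*coords), ps(*marks)
        w, wo = stratify_by_cooccupancy(sites, mark)
        got_with = {p.interval for p in w}
        expect_with = {
            p.interval for p in sites
            if any(p.interval.start < b and a < p.interval.end for a, b in marks)
        }
        assert got_with == expect_with
        assert {p.interval for p in w} | {p.interval for p in wo} == {p.interval for p in sites}
        assert not ({p.interval for p in w} & {p.interval for p in wo})


class TestOccupancyExpressionCorrelation:
    def test_monotone_relationship(self):
        occ = {f"g{i}": float(i) for i in range(15)}
        expr = {f"g{i}": float(i ** 2) for i in range(15)}
        assert occupancy_expression_correlation(occ, expr) == pytest.approx(1.0)

    def test_independent_pairing_within_null_envelope(self, rng):
        n = 200
        rhos = []
        for _ in range(20):
            occ = {f"g{i}": float(v) for i, v in enumerate(rng.random(n))}
            expr = {f"g{i}": float(v) for i, v in enumerate(rng.random(n))}
            rhos.append(occupancy_expression_correlation(occ, expr))
        # null rho is ~N(0, 1/sqrt(n-1))
        assert abs(np.mean(rhos)) < 3 / math.sqrt(n - 1)
        assert max(abs(r) for r in rhos) < 5 / math.sqrt(n - 1)

    def test_ties_match_rank_oracle(self):
        occ = {"a": 1.0, "b": 1.0, "c": 2.0, "d": 3.0, "e": 3.0,
               "f": 4.0, "g": 5.0, "h": 6.0, "i": 7.0, "j": 8.0}
        expr = {k: v for k, v in zip(occ, [2.0, 1.0, 1.0, 4.0, 5.0, 5.0, 6.0, 9.0, 8.0, 7.0])}
        got = occupancy_expression_correlation(occ, expr)
        x = stats.rankdata([occ[k] for k in sorted(occ)])
        y = stats.rankdata([expr[k] for k in sorted(occ)])
        assert got == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            occupancy_expression_correlation({"a": 1.0}, {"a": 2.0})


class TestConcordanceFraction:
    def test_all_matching_and_zero_rule(self):
        assert concordance_fraction(["a", "b"], "up", {"a": 0.3, "b": 1.0}) == 1.0
        assert concordance_fraction(["a", "b"], "up", {"a": 0.0, "b": 0.0}) == 0.0

    def test_planted_mixture_exact(self, rng):
        genes = [f"g{i}" for i in range(100)]
        ratio = {g: (1.0 if i < 80 else -1.0) for i, g in enumerate(genes)}
        assert concordance_fraction(genes, "up", ratio) == 0.80
        assert concordance_fraction(genes, "down", ratio) == 0.20


class TestPausingClassifier:
    @pytest.mark.parametrize(
        "prom,body,expect",
        [
            (0.8, -1.2, "pausing_consistent"),
            (-0.5, -0.9, "reduced_initiation"),
            (0.3, 0.2, "indeterminate"),
            (0.0, -1.0, "indeterminate"),
        ],
    )
    def test_decision_table(self, prom, body, expect):
        call = classify_repression_mechanism("g", prom, body, "down")
        assert call.mechanism == expect

    def test_up_gene_rejected(self):
        with pytest.raises(ValueError):
            classify_repression_mechanism("g", 1.0, -1.0, "up")


def ranksum_oracle(x, y):
    """Full enumeration of group assignments (midranks), independent route."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    dev = abs(w - mean)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mean) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_exact_small_example(self):
        w, p, method = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert method == "exact"
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p, _ = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_exact_matches_enumeration_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 6, size=5).astype(float)
            y = rng.integers(0, 6, size=6).astype(float)
            _, p, method = rank_sum_test(x, y)
            assert method == "exact"
            assert p == pytest.approx(ranksum_oracle(x, y), abs=1e-12)

    def test_normal_approx_close_to_exact_at_boundary(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 9)
        _, p_exact, _ = rank_sum_test(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert abs(p_exact - res.pvalue) < 0.01

    def test_planted_shift_strongly_significant(self, rng):
        x = rng.normal(-1, 0.5, 50)
        y = rng.normal(0, 0.5, 50)
        _, p, method = rank_sum_test(x, y)
        assert method == "normal"
        assert p < 0.001


class TestStrata:
    def test_strata_bounds_exclusive_and_disjoint(self):
        genes = [gene("near", 1000), gene("mid", 60_000), gene("far", 300_000)]
        sites = ps((0, 100))
        near, far = assign_strata(genes, sites)
        assert near == ["near"] and far == ["far"]  # mid excluded

    def test_group_size_and_disjointness_errors(self):
        ratios = {f"g{i}": float(i) for i in range(8)}
        with pytest.raises(ValueError):
            stratified_ratio_test(ratios, ["g0", "g1"], ["g2", "g3", "g4"])
        with pytest.raises(ValueError):
            stratified_ratio_test(ratios, ["g0", "g1", "g2"], ["g2", "g3", "g4"])

    def test_stratified_test_detects_planted_shift(self, rng):
        near = {f"n{i}": float(v) for i, v in enumerate(rng.normal(-1, 0.5, 40))}
        far = {f"f{i}": float(v) for i, v in enumerate(rng.normal(0, 0.5, 40))}
        ratios = {**near, **far}
        res = stratified_ratio_test(ratios, list(near), list(far))
        assert res.p < 0.001
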