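"""Responsive-gene filtering and cross-treatment concordance statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from cistrodyn.concordance import (
    filter_responsive,
    high_confidence_intersection,
    hypergeom_overlap_p,
    overlap_concordance,
    percent_concordant,
    read_de_table,
    responsive_counts,
    round_half_away,
    signed_fold_from_log2,
)
from cistrodyn.simulate import (
    SimulationConfig,
    make_genome_and_genes,
    simulate_expression_with_proximity,
    simulate_occupancy,
)


def table(genes):
    """genes: list of (gene_id, fold, padj)."""
    return pd.DataFrame(genes, columns=["gene_id", "fold_change", "padj"])


BASIC = table([("g1", 2.5, 0.001), ("g2", -1.8, 0.001), ("g3", -2.2, 0.5)])


class TestFiltering:
    def test_cutoff_rule(self):
        up = filter_responsive(BASIC, 0.01, 2.0, "up")
        down = filter_responsive(BASIC, 0.01, 2.0, "down")
        assert set(up.members) == {"g1"} and len(down) == 0

    def test_relaxed_fold_cutoff(self):
        up = filter_responsive(BASIC, 0.01, 1.5, "up")
        down = filter_responsive(BASIC, 0.01, 1.5, "down")
        assert set(up.members) == {"g1"} and set(down.members) == {"g2"}

    def test_fold_bound_inclusive_p_strict(self):
        t = table([("a", 2.0, 0.005), ("b", 2.0, 0.01)])
        got = filter_responsive(t, 0.01, 2.0, "up")
        assert set(got.members) == {"a"}

    def test_missing_columns_schema_error(self):
        with pytest.raises(ValueError, match="missing"):
            filter_responsive(pd.DataFrame({"gene_id": []}), 0.01, 2.0, "up")

    def test_counts_monotone_in_cutoffs(self, rng):
        t = table([
            (f"g{i}", float(np.sign(rng.standard_normal()) * rng.uniform(1, 5)),
             float(rng.uniform(0, 0.05)))
            for i in range(200)
        ])
        u15, d15 = responsive_counts(t, 0.01, 1.5)
        u20, d20 = responsive_counts(t, 0.01, 2.0)
        assert u15 >= u20 and d15 >= d20
        u_loose, d_loose = responsive_counts(t, 0.05, 2.0)
        assert u_loose >= u20 and d_loose >= d20

    def test_empty_table(self):
        assert responsive_counts(table([])) == (0, 0)

    def test_planted_counts_match_generator_bookkeeping(self):
        cfg = SimulationConfig(seed=3)
        genome, genes, _ = make_genome_and_genes(cfg, with_sequence=False)
        occ = simulate_occupancy(cfg, genome)
        de, truth, _ = simulate_expression_with_proximity(cfg, genes, occ["peaks"], genome)
        n_up, n_down = responsive_counts(de, 0.01, 2.0)
        assert n_up == (truth["label"] == "up").sum()
        assert n_down == (truth["label"] == "down").sum()


class TestLog2Conversion:
    def test_signed_linear_mapping(self):
        assert signed_fold_from_log2(1.0) == 2.0
        assert signed_fold_from_log2(-1.0) == -2.0
        assert signed_fold_from_log2(0.0) == 1.0

    def test_read_de_table_with_log2fc(self, tmp_path):
        f = tmp_path / "de.tsv"
        f.write_text("gene_id\tlog2fc\tpadj\ng1\t2.0\t0.001\ng2\t-1.0\t0.5\n")
        df = read_de_table(f)
        assert list(df["fold_change"]) == [4.0, -2.0]


class TestIntersection:
    def test_identity_disjoint_partial(self):
        a = filter_responsive(table([("x", 3, 0.001), ("y", 3, 0.001)]), direction="up")
        b = filter_responsive(table([("y", 3, 0.001), ("z", 3, 0.001)]), direction="up")
        assert set(high_confidence_intersection(a, b).members) == {"y"}
        assert set(high_confidence_intersection(a, a).members) == {"x", "y"}

    def test_direction_mismatch_rejected(self):
        a = filter_responsive(BASIC, direction="up")
        b = filter_responsive(BASIC, direction="down")
        with pytest.raises(ValueError):
            high_confidence_intersection(a, b)


class TestHypergeometric:
    def test_matches_exhaustive_pmf_enumeration(self):
        # 10-gene universe: sum the pmf directly as an independent oracle
        M, n_a, n_b = 10, 4, 5
        for k in range(0, 5):
            expect = sum(
                math.comb(n_a, j) * math.comb(M - n_a, n_b - j) / math.comb(M, n_b)
                for j in range(k, min(n_a, n_b) + 1)
            )
            assert hypergeom_overlap_p(k, n_a, n_b, M) == pytest.approx(expect, abs=1e-12)

    def test_larger_universe_against_oracle(self):
        M, n_a, n_b, k = 5000, 300, 200, 30
        expect = sum(
            math.comb(n_a, j) * math.comb(M - n_a, n_b - j) / math.comb(M, n_b)
            for j in range(k, min(n_a, n_b) + 1)
        )
        assert hypergeom_overlap_p(k, n_a, n_b, M) == pytest.approx(expect, rel=1e-9)

    def test_universe_too_small(self):
        with pytest.raises(ValueError):
            hypergeom_overlap_p(2, 5, 5, 4)


def build_tables(concordant, discordant, n_a_extra, n_b_extra, seed=0):
    """Two DE tables whose responsive overlap has the given structure."""
    rng = np.random.default_rng(seed)
    rows_a, rows_b = [], []
    gid = 0
    for _ in range(concordant):
        sign = 1 if rng.random() < 0.5 else -1
        rows_a.append((f"g{gid}", sign * 3.0, 1e-5))
        rows_b.append((f"g{gid}", sign * 2.5, 1e-5))
        gid += 1
    for _ in range(discordant):
        sign = 1 if rng.random() < 0.5 else -1
        rows_a.append((f"g{gid}", sign * 3.0, 1e-5))
        rows_b.append((f"g{gid}", -sign * 2.5, 1e-5))
        gid += 1
    for _ in range(n_a_extra):  # responsive only in a
        rows_a.append((f"g{gid}", 3.0, 1e-5))
        rows_b.append((f"g{gid}", 1.0, 0.9))
        gid += 1
    for _ in range(n_b_extra):  # responsive only in b
        rows_a.append((f"g{gid}", 1.0, 0.9))
        rows_b.append((f"g{gid}", -3.0, 1e-5))
        gid += 1
    for _ in range(100):  # nulls
        rows_a.append((f"g{gid}", 1.0, 0.9))
        rows_b.append((f"g{gid}", 1.0, 0.9))
        gid += 1
    return table(rows_a), table(rows_b)


class TestOverlapConcordance:
    def test_reported_style_percentages(self):
        a, b = build_tables(29, 3, 92, 10)
        res = overlap_concordance(a, b)
        assert (res.overlap, res.concordant, res.discordant) == (32, 29, 3)
        assert res.percent_concordant == 90.6
        assert res.overlap_percent == pytest.approx(25.8)

    def test_percent_rounding_convention(self):
        assert percent_concordant(70, 119) == 37.0
        assert percent_concordant(222, 553) == 28.6
        assert round_half_away(0.05, 1) == 0.1  # half goes away from zero
        assert round_half_away(-0.05, 1) == -0.1

    def test_overlap_equals_concordant_plus_discordant(self, rng):
        a, b = build_tables(17, 6, 4, 9, seed=5)
        res = overlap_concordance(a, b)
        assert res.overlap == res.concordant + res.discordant

    def test_sign_flip_symmetries(self):
        a, b = build_tables(12, 7, 3, 3)
        base = overlap_concordance(a, b)
        both = overlap_concordance(
            a.assign(fold_change=-a.fold_change), b.assign(fold_change=-b.fold_change)
        )
        assert both.percent_concordant == base.percent_concordant
        one = overlap_concordance(a.assign(fold_change=-a.fold_change), b)
        assert (one.concordant, one.discordant) == (base.discordant, base.concordant)

    def test_universe_smaller_than_union_rejected(self):
        a, b = build_tables(5, 0, 5, 5)
        with pytest.raises(ValueError):
            overlap_concordance(a, b, universe=10)
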