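"""Ohnolog enrichment, resampled co-expression medians, and level tests."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svpop.duplication import (
    OhnologTable,
    expression_correlation_resample,
    expression_level_tests,
    gene_overlap_flags,
    ohnolog_enrichment,
)
from svpop.simulate import SimConfig, simulate_expression, simulate_ohnolog_table

from conftest import make_catalog


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestGeneOverlapFlags:
    def test_overlap_boundary_and_type_filter(self):
        genes = genes_frame(
            [("g1", "chr1", 150, 400), ("g2", "chr1", 200, 400)]
        )
        cat = make_catalog([("a", "chr1", 100, 200, "DUP")])
        flags = gene_overlap_flags(cat, genes)
        assert flags["g1"] and not flags["g2"]  # half-open: [100,200) vs [200,400)
        flags_del = gene_overlap_flags(cat, genes, svtype="DEL")
        assert not flags_del.any()


def fisher_enumeration(table):
    """Two-sided Fisher P by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {
        x: comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs + 1e-12)


class TestOhnologEnrichment:
    @staticmethod
    def make_inputs(o_hit, o_genes, s_hit, s_tot):
        """o_genes paired genes (even count) with the first o_hit flagged;
        s_tot singletons with the first s_hit flagged."""
        genes, pairs, singles, flags = [], [], [], {}
        names = [f"o{i}" for i in range(o_genes)]
        for i, g in enumerate(names):
            genes.append((g, "chr1", 0, 10))
            flags[g] = i < o_hit
        for i in range(0, o_genes, 2):
            pairs.append({"gene_a": names[i], "gene_b": names[i + 1]})
        for i in range(s_tot):
            g = f"s{i}"
            genes.append((g, "chr1", 0, 10))
            singles.append(g)
            flags[g] = i < s_hit
        table = OhnologTable(genes_frame(genes), pd.DataFrame(pairs), singles)
        return pd.Series(flags), table

    def test_two_by_two_example_matches_enumeration(self):
        # (ohnolog, singleton) x (overlapped, not) = [[2,0],[0,2]]
        flags, table = self.make_inputs(2, 2, 0, 2)
        res = ohnolog_enrichment(flags, table)
        assert res.table.tolist() == [[2, 0], [0, 2]]
        assert res.pvalue == pytest.approx(1 / 3)
        assert np.isinf(res.odds_ratio)

    def test_no_association_gives_or_one_p_one(self):
        flags, table = self.make_inputs(2, 4, 2, 4)
        res = ohnolog_enrichment(flags, table)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_planted_bias_detected_in_simulation(self):
        rng = np.random.default_rng(77)
        n_pairs, n_single = 700, 600
        genes, pairs, singles, flags = [], [], [], {}
        for i in range(n_pairs):
            a, b = f"p{i}a", f"p{i}b"
            genes += [(a, "chr1", 0, 10), (b, "chr1", 0, 10)]
            pairs.append({"gene_a": a, "gene_b": b})
            flags[a] = bool(rng.random() < 0.30)
            flags[b] = bool(rng.random() < 0.30)
        for i in range(n_single):
            g = f"s{i}"
            genes.append((g, "chr1", 0, 10))
            singles.append(g)
            flags[g] = bool(rng.random() < 0.20)
        table = OhnologTable(genes_frame(genes), pd.DataFrame(pairs), singles)
        res = ohnolog_enrichment(pd.Series(flags), table)
        assert res.odds_ratio > 1 and res.pvalue < 0.05

    def test_fisher_matches_enumeration_on_all_small_margins(self):
        """scipy's two-sided Fisher equals exhaustive enumeration for every
        2x2 table with N <= 12."""
        checked = 0
        for n in range(2, 13):
            for row1 in range(1, n):
                for col1 in range(1, n):
                    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
                    for a in range(lo, hi + 1):
                        t = [[a, row1 - a], [col1 - a, n - row1 - col1 + a]]
                        _, p = stats.fisher_exact(t)
                        assert p == pytest.approx(fisher_enumeration(t), abs=1e-9)
                        checked += 1
        assert checked > 1000


@pytest.fixture(scope="module")
def table_and_expr():
    cfg = SimConfig(n_ohnolog_pairs=120, n_singletons=30, expr_rho=0.6, seed=42)
    table = simulate_ohnolog_table(cfg)
    expr = simulate_expression(table, [], cfg)
    return table, expr


class TestCorrelationResample:
    def test_degenerate_subset_all_pairs_gives_p_zero(self, table_and_expr):
        table, expr = table_and_expr
        obs, p = expression_correlation_resample(table, expr, table.pairs,
                                                 n_resample=50, seed=1)
        assert p == 0.0  # every resampled median equals the observed one

    def test_reproducible_and_invariant_to_pair_order(self, table_and_expr):
        table, expr = table_and_expr
        subset = table.pairs.iloc[:20]
        r1 = expression_correlation_resample(table, expr, subset, 200, seed=3)
        r2 = expression_correlation_resample(
            table, expr, subset.iloc[::-1], 200, seed=3
        )
        assert r1 == r2

    def test_low_correlation_subset_detected(self):
        cfg = SimConfig(
            n_ohnolog_pairs=400, n_singletons=10, expr_rho=0.6,
            expr_rho_sv=0.3, expr_sv_effect=0.5, seed=55,
        )
        table = simulate_ohnolog_table(cfg)
        overlapped = list(table.pairs["gene_a"].iloc[:80])
        expr = simulate_expression(table, overlapped, cfg)
        sv_pairs = table.pairs.iloc[:80]
        obs, p = expression_correlation_resample(table, expr, sv_pairs,
                                                 n_resample=500, seed=6)
        assert p < 0.05  # observed median sits in the null's lower tail

    def test_constant_member_pair_dropped_with_warning(self, table_and_expr):
        table, expr = table_and_expr
        expr = expr.copy()
        expr.loc[table.pairs["gene_a"].iloc[0]] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            expression_correlation_resample(table, expr, table.pairs.iloc[:10],
                                            n_resample=20, seed=0)


class TestExpressionLevelTests:
    def test_wilcoxon_exact_small_sample_value(self):
        """{1,2,3} vs {4,5,6}: complete separation, exact two-sided P =
        2/C(6,3) = 0.1 (enumeration over all rank assignments)."""
        res = stats.mannwhitneyu([1, 2, 3], [4, 5, 6],
                                 alternative="two-sided", method="exact")
        # enumeration oracle
        values = [1, 2, 3, 4, 5, 6]
        u_obs = 0  # all pairwise comparisons favour group 2
        count = 0
        total = 0
        for pick in combinations(range(6), 3):
            g1 = [values[i] for i in pick]
            g2 = [values[i] for i in range(6) if i not in pick]
            u = sum(1 for x in g1 for y in g2 if x > y)
            total += 1
            if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
                count += 1
        assert count / total == pytest.approx(0.1)
        assert res.pvalue == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = stats.mannwhitneyu([1, 2, 3], [1, 2, 3], alternative="two-sided")
        assert res.pvalue == pytest.approx(1.0)

    def test_sv_effect_rejects_within_discordant_pairs(self):
        cfg = SimConfig(
            n_ohnolog_pairs=500, n_singletons=10, expr_rho=0.6,
            expr_sv_effect=0.5, seed=88,
        )
        table = simulate_ohnolog_table(cfg)
        overlapped = set(table.pairs["gene_a"])  # all pairs discordant
        expr = simulate_expression(table, overlapped, cfg)
        flags = pd.Series(
            {g: g in overlapped for g in table.genes["gene_id"]}
        )
        results = {t.name: t for t in expression_level_tests(table, expr, flags)}
        t1 = results["overlapped_vs_partner"]
        assert t1.pvalue < 0.01 and t1.n1 == 500

    def test_empty_group_skipped_with_reason(self):
        cfg = SimConfig(n_ohnolog_pairs=20, n_singletons=5, seed=9)
        table = simulate_ohnolog_table(cfg)
        expr = simulate_expression(table, [], cfg)
        flags = pd.Series(False, index=list(table.genes["gene_id"]))
        results = {t.name: t for t in expression_level_tests(table, expr, flags)}
        assert results["overlapped_vs_partner"].skipped_reason == "empty group"
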