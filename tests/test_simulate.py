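"""Generator contracts: determinism, conservation, planted structure, and
parameter recovery at reduced scale."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svpop.errors import ConfigurationError
from svpop.regions import RegionSet, find_high_depth_regions
from svpop.simulate import (
    SimConfig,
    simulate_amplicon_pileups,
    simulate_cohort,
    simulate_coverage,
    simulate_curation_labels,
    simulate_expression,
    simulate_ohnolog_table,
    simulate_sv_catalog,
)
from svpop.svset import estimate_fdr


class TestConfigValidation:
    def test_fraction_out_of_range_names_field(self):
        with pytest.raises(ConfigurationError, match="spike_fraction"):
            SimConfig(spike_fraction=1.5)

    def test_latitudes_must_match_populations(self):
        with pytest.raises(ConfigurationError, match="latitudes"):
            SimConfig(n_populations=3, latitudes=(60.0, 62.0))

    def test_too_few_tissues_rejected(self):
        with pytest.raises(ConfigurationError, match="tissues"):
            SimConfig(n_tissues=2)


class TestCohort:
    def test_empty_config_yields_empty_outputs(self):
        cfg = SimConfig(n_sv={"DEL": 0, "DUP": 0, "INV": 0}, seed=1)
        gm, samples, truth = simulate_cohort(cfg)
        assert gm.n_sv == 0 and len(truth.sv) == 0
        assert gm.n_samples == len(samples) == cfg.n_wild + cfg.n_farmed

    def test_determinism_and_conservation(self, small_config):
        gm1, s1, t1 = simulate_cohort(small_config)
        gm2, s2, t2 = simulate_cohort(small_config)
        assert (gm1.codes == gm2.codes).all()
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1.sv, t2.sv)
        assert gm1.n_sv == sum(small_config.n_sv.values())
        assert t1.sv["sv_id"].is_unique

    def test_planted_outliers_shift_farmed_frequency(self, small_config):
        _, _, truth = simulate_cohort(small_config)
        planted = truth.sv["is_planted_outlier"]
        assert planted.sum() == small_config.n_planted_outliers
        shift = truth.sv["freq_farmed"] - truth.sv["freq_pop0"]
        assert shift[planted].mean() > shift[~planted].mean() + 0.15

    def test_balding_nichols_mean_theta_near_F(self):
        """Two groups at divergence F = 0.10: the average per-SV theta over
        2000 SVs recovers F within +/- 0.02 (Monte-Carlo check against the
        Balding-Nichols expectation E(theta) ~ F)."""
        from svpop.popgen import fst_outlier_scan

        cfg = SimConfig(
            n_wild=200, n_farmed=0, n_populations=2, latitudes=(60.0, 65.0),
            divergence_F=0.10, within_lineage_F_fraction=0.0, cline_strength=0.0,
            n_sv={"DEL": 2000}, n_planted_outliers=0, missing_rate=0.0, seed=42,
        )
        gm, samples, _ = simulate_cohort(cfg)
        res, _ = fst_outlier_scan(
            gm, samples["population"].to_numpy(), n_perm=1, seed=0
        )
        mean_theta = res.loc[~res["excluded_monomorphic"], "theta"].mean()
        assert mean_theta == pytest.approx(0.10, abs=0.02)


class TestCatalog:
    def test_spike_fraction_one_puts_all_deletions_in_spike(self):
        cfg = SimConfig(n_sv={"DEL": 200}, spike_fraction=1.0, seed=2)
        cat = simulate_sv_catalog(cfg)
        assert cat.df["size"].between(1432, 1436).all()

    def test_spike_fraction_zero_leaves_no_excess_mass(self):
        """Chi-square on binned deletion sizes: the 1432-1436 bin should not
        stand out against its neighbours when no spike is planted."""
        cfg = SimConfig(n_sv={"DEL": 10_000}, spike_fraction=0.0, seed=3)
        sizes = simulate_sv_catalog(cfg).df["size"].to_numpy()
        bins = np.arange(1382, 1492, 5)  # 5-bp bins around the spike window
        counts, _ = np.histogram(sizes, bins)
        if counts.sum() >= 50:
            _, p = stats.chisquare(counts)
            assert p > 0.001
        spike = ((sizes >= 1432) & (sizes <= 1436)).mean()
        neighbour = ((sizes >= 1437) & (sizes <= 1441)).mean()
        assert spike < 3 * max(neighbour, 1 / len(sizes)) + 0.001

    def test_type_counts_and_bounds(self):
        cfg = SimConfig(n_sv={"DEL": 50, "DUP": 10, "INV": 5}, seed=4)
        cat = simulate_sv_catalog(cfg)
        assert cat.type_counts().to_dict() == {"DEL": 50, "DUP": 10, "INV": 5}
        genome = dict(cfg.genome)
        for rec in cat.df.itertuples(index=False):
            assert 0 <= rec.start < rec.end <= genome[rec.chrom]


class TestCoverage:
    def test_planted_window_satisfies_rule_and_determinism(self):
        cfg = SimConfig(
            n_wild=120, n_farmed=30, n_populations=1, latitudes=(62.0,),
            depth_high=150.0, high_region_n_samples=120, n_high_regions=2,
            genome=(("chr1", 200_000),), seed=5,
        )
        prof1 = simulate_coverage(cfg)
        prof2 = simulate_coverage(cfg)
        assert (prof1.depth == prof2.depth).all()
        found = find_high_depth_regions(prof1, 100, 100, 100)
        # every planted region is recovered
        from svpop.intervals import overlaps_merged

        hits = overlaps_merged(prof1.truth_regions.df, found.df)
        assert hits.all()

    def test_no_high_depth_regions_at_baseline_depth(self):
        """P(Poisson(8.1) >= 100) ~ 1e-58: without planted regions the
        detector must come back empty."""
        cfg = SimConfig(
            n_wild=120, n_farmed=30, n_populations=1, latitudes=(62.0,),
            n_high_regions=0, genome=(("chr1", 500_000),), seed=6,
        )
        prof = simulate_coverage(cfg)
        assert len(find_high_depth_regions(prof, 100, 100)) == 0

    def test_window_larger_than_chromosome_rejected(self):
        cfg = SimConfig(genome=(("chr1", 500),), window_size=1000,
                        n_high_regions=0, seed=0)
        with pytest.raises(ConfigurationError, match="window_size"):
            simulate_coverage(cfg)


class TestCurationLabels:
    def test_fdr_complex_one_marks_every_in_region_call_false(self):
        cfg = SimConfig(n_sv={"DEL": 300}, fdr_complex=1.0,
                        n_planted_outliers=0, seed=7)
        cat = simulate_sv_catalog(cfg)
        regions = RegionSet.from_intervals(
            [(c, 0, ln) for c, ln in cfg.genome]
        )
        labels = simulate_curation_labels(cat, regions, cfg)
        assert (labels["region_class"] == "complex").all()
        assert (~labels["is_true_call"]).all()
        assert labels["label"].isin(["no", "maybe"]).all()

    def test_configured_fdr_recovered_within_binomial_error(self):
        cfg = SimConfig(n_sv={"DEL": 10_000}, fdr_normal=0.85,
                        n_planted_outliers=0, seed=8)
        cat = simulate_sv_catalog(cfg)
        labels = simulate_curation_labels(cat, RegionSet.empty(), cfg)
        (overall,) = [r for r in estimate_fdr(labels) if r.stratum == "overall"]
        assert overall.fdr == pytest.approx(0.85, abs=0.01)

    def test_empty_region_set_uses_normal_rate_only(self):
        cfg = SimConfig(n_sv={"DEL": 500}, fdr_normal=0.0, fdr_complex=1.0,
                        n_planted_outliers=0, seed=9)
        cat = simulate_sv_catalog(cfg)
        labels = simulate_curation_labels(cat, RegionSet.empty(), cfg)
        assert (labels["label"] == "yes").all()


class TestAmpliconPileups:
    def test_noise_free_homozygote_all_alt(self, small_config):
        cfg = SimConfig.from_dict(
            {**small_config.to_dict(), "amplicon_error_rate": 0.0,
             "amplicon_dropout_rate": 0.0, "amplicon_unassigned_rate": 0.0}
        )
        gm, _, _ = simulate_cohort(cfg)
        pileups = simulate_amplicon_pileups(gm, cfg)
        hom = pileups[pileups["true_gt"] == "1/1"]
        assert (hom["n_alt"] == hom["n_total"]).all()

    def test_het_alt_fraction_within_binomial_ci(self, small_config):
        cfg = SimConfig.from_dict(
            {**small_config.to_dict(), "amplicon_error_rate": 0.0,
             "amplicon_dropout_rate": 0.0, "amplicon_unassigned_rate": 0.0,
             "n_amplicons": 2000, "n_sv": {"DEL": 200}}
        )
        gm, _, _ = simulate_cohort(cfg)
        pileups = simulate_amplicon_pileups(gm, cfg)
        het = pileups[pileups["true_gt"] == "0/1"]
        frac = het["n_alt"].sum() / het["n_total"].sum()
        se = 0.5 / np.sqrt(het["n_total"].sum())
        assert abs(frac - 0.5) < 5 * se

    def test_dropout_produces_sub_50x_failures(self, small_config):
        cfg = SimConfig.from_dict(
            {**small_config.to_dict(), "amplicon_dropout_rate": 0.3,
             "n_amplicons": 400}
        )
        gm, _, _ = simulate_cohort(cfg)
        pileups = simulate_amplicon_pileups(gm, cfg)
        assert (pileups["n_total"] < 50).any()


class TestExpression:
    def test_perfect_correlation_no_noise(self):
        cfg = SimConfig(n_ohnolog_pairs=10, n_singletons=0, expr_rho=1.0,
                        expr_rho_sv=1.0, seed=10)
        table = simulate_ohnolog_table(cfg)
        expr = simulate_expression(table, [], cfg)
        for a, b in zip(table.pairs["gene_a"], table.pairs["gene_b"]):
            rho, _ = stats.spearmanr(expr.loc[a], expr.loc[b])
            assert rho == pytest.approx(1.0)

    def test_rho_recovered_at_scale(self):
        cfg = SimConfig(n_ohnolog_pairs=2000, n_singletons=0, expr_rho=0.6,
                        seed=11)
        table = simulate_ohnolog_table(cfg)
        expr = simulate_expression(table, [], cfg)
        rhos = [
            stats.spearmanr(expr.loc[a], expr.loc[b]).statistic
            for a, b in zip(table.pairs["gene_a"], table.pairs["gene_b"])
        ]
        assert np.median(rhos) == pytest.approx(0.6, abs=0.05)

    def test_sv_effect_halves_overlapped_copy_abundance(self):
        cfg = SimConfig(n_ohnolog_pairs=2000, n_singletons=0,
                        expr_sv_effect=0.5, seed=12)
        table = simulate_ohnolog_table(cfg)
        overlapped = list(table.pairs["gene_a"])
        expr = simulate_expression(table, overlapped, cfg)
        # ratio of group means over all pairs
        ratio = (
            expr.loc[table.pairs["gene_a"]].to_numpy().mean()
            / expr.loc[table.pairs["gene_b"]].to_numpy().mean()
        )
        assert ratio == pytest.approx(0.5, rel=0.1)

    def test_all_values_nonnegative_and_shape(self):
        cfg = SimConfig(n_ohnolog_pairs=50, n_singletons=20, seed=13)
        table = simulate_ohnolog_table(cfg)
        expr = simulate_expression(table, [], cfg)
        assert expr.shape == (120, cfg.n_tissues)
        assert (expr.to_numpy() >= 0).all()
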