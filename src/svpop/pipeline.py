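"""End-to-end orchestration: simulate inputs, filter, collapse, estimate FDR,
validate, scan for F_ST outliers, test ohnolog enrichment, annotate.

`run_pipeline` executes the stages in dependency order, writes every output
as a text file (VCF/BED/TSV/JSON) under ``out_dir``, and records a manifest
with parameters, seeds and SHA-256 hashes of all produced files. A rerun
with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from svpop import annotation, duplication, popgen, regions, svset, validation
from svpop.errors import ConfigurationError
from svpop.simulate import (
    SimConfig,
    simulate_amplicon_pileups,
    simulate_cohort,
    simulate_coverage,
    simulate_curation_labels,
    simulate_expression,
    simulate_ohnolog_table,
    simulate_peaks,
    simulate_sv_catalog,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "filter_regions",
    "collapse",
    "fdr",
    "validate",
    "fst_scan",
    "ohnolog_test",
    "annotate",
)


@dataclass
class PipelineConfig:
    """Stage toggles plus all stage parameters.

    Analysis stages consume the synthetic inputs written by the simulate
    stage; disabling ``simulate`` requires the input files to already exist
    in ``out_dir``.
    """

    out_dir: str = "svpop_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    sim: SimConfig = field(default_factory=SimConfig)
    # region filtering
    depth_threshold: float = 100.0
    sample_threshold: int = 100
    merge_gap: int = 100
    # collapse
    reciprocal: float = 0.9
    # validation
    min_cov: int = 50
    hom_frac: float = 0.9
    het_frac: float = 0.1
    # fst scan
    n_perm: int = 200
    alpha: float = 0.01
    quantile: float = 0.997
    # ohnolog / annotation
    n_resample: int = 1000
    gene_flank: int = 5000
    peak_flank: int = 3000
    specificity_threshold: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        # the simulation and scan must not share a random stream
        self.sim.seed = int(self.sim.seed)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "stages": dict(self.stages),
            "sim": self.sim.to_dict(),
            "depth_threshold": self.depth_threshold,
            "sample_threshold": self.sample_threshold,
            "merge_gap": self.merge_gap,
            "reciprocal": self.reciprocal,
            "min_cov": self.min_cov,
            "hom_frac": self.hom_frac,
            "het_frac": self.het_frac,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "quantile": self.quantile,
            "n_resample": self.n_resample,
            "gene_flank": self.gene_flank,
            "peak_flank": self.peak_flank,
            "specificity_threshold": self.specificity_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run enabled stages in order; return (and write) the run manifest.

    On a stage failure, downstream stages are skipped and a partial
    manifest is still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stages_completed": [],
        "stages_skipped": [],
        "files": {},
        "results": {},
        "error": None,
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    state: dict = {}
    failed = False
    for stage in STAGES:
        if not config.stages.get(stage, True):
            manifest["stages_skipped"].append(stage)
            continue
        if failed:
            manifest["stages_skipped"].append(stage)
            continue
        try:
            _run_stage(stage, config, out, state, manifest, record)
            manifest["stages_completed"].append(stage)
        except Exception as exc:  # noqa: BLE001 - report and stop downstream
            logger.error("stage %s failed: %s", stage, exc)
            manifest["error"] = {
                "stage": stage,
                "message": str(exc),
                "traceback": traceback.format_exc(),
            }
            failed = True
            manifest["stages_skipped"].append(stage)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stage(stage, config: PipelineConfig, out: Path, state, manifest, record):
    sim = config.sim
    if stage == "simulate":
        gm, samples, truth = simulate_cohort(sim)
        catalog = simulate_sv_catalog(sim)
        coverage = simulate_coverage(sim)
        ohno = simulate_ohnolog_table(sim)
        peaks = simulate_peaks(ohno.genes, sim)
        state.update(
            gm=gm, samples=samples, truth=truth, catalog=catalog,
            coverage=coverage, ohnologs=ohno, peaks=peaks,
        )
        svset.write_vcf(out / "svs.vcf", catalog,
                        gm.subset_svs(list(catalog.df["id"])), list(sim.genome))
        samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        truth.sv.to_csv(out / "truth_sv.tsv", sep="\t", index=False)
        coverage.write_tsv(out / "coverage.tsv")
        ohno.write_tsv(out / "ohnologs.tsv")
        peaks.to_csv(out / "peaks.bed", sep="\t", header=False, index=False)
        for name in ("svs.vcf", "samples.tsv", "truth_sv.tsv", "coverage.tsv",
                     "ohnologs.tsv", "peaks.bed"):
            record(name, out / name)
    elif stage == "filter_regions":
        high = regions.find_high_depth_regions(
            state["coverage"],
            config.depth_threshold,
            min(config.sample_threshold, len(state["coverage"].sample_ids)),
            config.merge_gap,
        )
        exclusion = high  # assembly gaps would be unioned here if provided
        kept, excluded = regions.exclude_overlapping(state["catalog"], exclusion)
        state.update(exclusion=exclusion, catalog=kept, excluded=excluded)
        high.write_bed(out / "high_depth.bed")
        exclusion.write_bed(out / "exclusion.bed")
        excluded.df.to_csv(out / "excluded_svs.tsv", sep="\t", index=False)
        for name in ("high_depth.bed", "exclusion.bed", "excluded_svs.tsv"):
            record(name, out / name)
        manifest["results"]["n_excluded_by_region"] = len(excluded)
    elif stage == "collapse":
        kept, removed = svset.collapse_redundant(state["catalog"], config.reciprocal)
        state["catalog"] = kept
        pd.Series(removed, name="removed_id").to_csv(
            out / "collapsed_removed.tsv", sep="\t", index=False
        )
        record("collapsed_removed.tsv", out / "collapsed_removed.tsv")
        manifest["results"]["n_collapsed"] = len(removed)
    elif stage == "fdr":
        labels = simulate_curation_labels(
            state["catalog"], state["exclusion"], sim, state["truth"]
        )
        state["labels"] = labels
        reports = svset.estimate_fdr(labels)
        frame = pd.DataFrame(
            [
                {"stratum": r.stratum, "n_total": r.n_total,
                 "n_low_confidence": r.n_low_confidence, "fdr": r.fdr}
                for r in reports
            ]
        )
        labels.to_csv(out / "curation_labels.tsv", sep="\t", index=False)
        frame.to_csv(out / "fdr_report.tsv", sep="\t", index=False)
        record("curation_labels.tsv", out / "curation_labels.tsv")
        record("fdr_report.tsv", out / "fdr_report.tsv")
        manifest["results"]["fdr_overall"] = float(frame.iloc[-1]["fdr"])
        # keep only high-confidence calls downstream
        keep_ids = labels.loc[labels["label"] == "yes", "call_id"]
        state["catalog"] = state["catalog"].subset(keep_ids)
    elif stage == "validate":
        gm = state["gm"].subset_svs(list(state["catalog"].df["id"]))
        pileups = simulate_amplicon_pileups(gm, sim)
        classified = validation.classify_pileups(
            pileups, config.min_cov, config.hom_frac, config.het_frac
        )
        report = validation.concordance_report(
            classified,
            svtypes=state["catalog"].df.set_index("id")["svtype"],
        )
        classified.to_csv(out / "amplicon_classified.tsv", sep="\t", index=False)
        report.per_type.to_csv(out / "concordance.tsv", sep="\t", index=False)
        record("amplicon_classified.tsv", out / "amplicon_classified.tsv")
        record("concordance.tsv", out / "concordance.tsv")
        overall = report.per_type[report.per_type["svtype"] == "overall"].iloc[0]
        manifest["results"]["presence_rate"] = float(overall["presence_rate"])
        manifest["results"]["genotype_rate"] = float(overall["genotype_rate"])
    elif stage == "fst_scan":
        gm = state["gm"].subset_svs(list(state["catalog"].df["id"]))
        labels = state["samples"]["origin"].to_numpy()
        res, null = popgen.fst_outlier_scan(
            gm, labels, config.n_perm, config.quantile, config.alpha,
            seed=config.seed + 1_000_003,
        )
        state["fst"] = res
        res.to_csv(out / "fst_results.tsv", sep="\t", index=False)
        pd.Series(null.pooled, name="null_theta").to_csv(
            out / "fst_null.tsv", sep="\t", index=False
        )
        record("fst_results.tsv", out / "fst_results.tsv")
        record("fst_null.tsv", out / "fst_null.tsv")
        manifest["results"]["n_outliers"] = int(res["is_outlier"].sum())
        manifest["results"]["fst_cutoff"] = float(null.global_cutoff)
    elif stage == "ohnolog_test":
        ohno = state["ohnologs"]
        flags = duplication.gene_overlap_flags(state["catalog"], ohno.genes)
        expr = simulate_expression(ohno, flags[flags].index, sim)
        state.update(flags=flags, expr=expr)
        enr = duplication.ohnolog_enrichment(flags, ohno)
        a_hit = flags.loc[ohno.pairs["gene_a"]].to_numpy()
        b_hit = flags.loc[ohno.pairs["gene_b"]].to_numpy()
        sv_pairs = ohno.pairs[a_hit | b_hit]
        rows = [
            {"test": enr.label, "statistic": enr.odds_ratio, "p": enr.pvalue}
        ]
        if len(sv_pairs) >= 2:
            obs, p = duplication.expression_correlation_resample(
                ohno, expr, sv_pairs, config.n_resample,
                seed=config.seed + 2_000_003,
            )
            rows.append({"test": "correlation_resample", "statistic": obs, "p": p})
        for t in duplication.expression_level_tests(ohno, expr, flags):
            rows.append({"test": t.name, "statistic": t.statistic, "p": t.pvalue})
        frame = pd.DataFrame(rows)
        expr.to_csv(out / "expression.tsv", sep="\t")
        frame.to_csv(out / "ohnolog_tests.tsv", sep="\t", index=False)
        record("expression.tsv", out / "expression.tsv")
        record("ohnolog_tests.tsv", out / "ohnolog_tests.tsv")
        manifest["results"]["ohnolog_odds_ratio"] = float(enr.odds_ratio)
    elif stage == "annotate":
        ohno = state["ohnologs"]
        links = annotation.link_svs_to_genes(
            state["catalog"], ohno.genes, config.gene_flank
        )
        spec_table = annotation.tissue_specificity(state["expr"])
        fst = state.get("fst")
        rows = []
        if fst is not None and fst["is_outlier"].any():
            outlier_ids = set(fst.loc[fst["is_outlier"], "sv_id"])
            linked_genes = links.loc[
                links["sv_id"].isin(outlier_ids), "gene_id"
            ].unique()
            tissue = state["expr"].columns[0]
            enr = annotation.brain_enrichment_tests(
                linked_genes, spec_table, state["expr"], tissue=tissue,
                threshold=config.specificity_threshold,
            )
            rows.append(
                {"test": f"{tissue}_specificity_hypergeom", "statistic": enr.k_specific_in_subset,
                 "p": enr.hypergeom_p}
            )
            rows.append(
                {"test": f"{tissue}_cpm_welch_t", "statistic": enr.t_statistic,
                 "p": enr.t_pvalue}
            )
            out_cat = state["catalog"].subset(outlier_ids)
            bg_cat = state["catalog"].subset(
                set(state["catalog"].df["id"]) - outlier_ids
            )
            if len(out_cat) and len(bg_cat) and len(state["peaks"]):
                atac = annotation.atac_overlap_test(
                    out_cat, bg_cat, state["peaks"], ohno.genes, config.peak_flank
                )
                rows.append(
                    {"test": atac.label, "statistic": atac.odds_ratio,
                     "p": atac.pvalue}
                )
        links.to_csv(out / "sv_gene_links.tsv", sep="\t", index=False)
        pd.DataFrame(rows).to_csv(out / "annotation_tests.tsv", sep="\t", index=False)
        record("sv_gene_links.tsv", out / "sv_gene_links.tsv")
        record("annotation_tests.tsv", out / "annotation_tests.tsv")
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown stage {stage}")
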