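"""Functional context of outlier SVs: gene linkage, tissue specificity,
and open-chromatin (ATAC) peak overlap.

Tissue specificity of a gene is the per-tissue fraction of its total
across-tissue abundance (bounded in [0, 1], summing to 1 across tissues);
genes whose across-tissue abundance sums below 1 are filtered before any
specificity-based test. Outlier-linked gene sets are tested for an excess
of tissue-specific genes (upper-tail hypergeometric at a specificity
threshold, default 0.5) and for elevated abundance in a focal tissue
(Welch two-sample t-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from svpop.errors import ConfigurationError
from svpop.duplication import EnrichmentResult
from svpop.intervals import overlap_pairs
from svpop.svset import SVCatalog


@dataclass
class SpecificityTable:
    """Per-gene tissue specificity indices and the low-abundance filter.

    ``indices`` covers retained genes only (rows sum to 1); ``totals`` and
    ``filtered`` cover every input gene.
    """

    indices: pd.DataFrame
    totals: pd.Series
    filtered: pd.Series


def tissue_specificity(
    expr: pd.DataFrame, min_total: float = 1.0
) -> SpecificityTable:
    """Normalize each gene's expression across tissues to a specificity index.

    index(g, t) = abundance(g, t) / sum_t abundance(g, t). Genes with total
    abundance < ``min_total`` (including all-zero genes) are flagged
    filtered and carry no indices.
    """
    if (expr.to_numpy() < 0).any():
        raise ConfigurationError("expression must be non-negative")
    totals = expr.sum(axis=1)
    filtered = totals < min_total
    retained = expr.loc[~filtered]
    indices = retained.div(totals.loc[~filtered], axis=0)
    return SpecificityTable(indices, totals, filtered)


@dataclass
class TissueEnrichmentResult:
    hypergeom_p: float
    k_specific_in_subset: int
    K_specific_in_population: int
    n_subset: int
    N_population: int
    t_statistic: float
    t_pvalue: float
    mean_subset: float
    mean_population: float
    skipped_reason: str | None = None


def brain_enrichment_tests(
    subset_genes,
    spec: SpecificityTable,
    expr: pd.DataFrame,
    tissue: str = "brain",
    threshold: float = 0.5,
) -> TissueEnrichmentResult:
    """Is a gene subset enriched for tissue-specific, highly expressed genes?

    Population = genes retained after the low-abundance filter. The
    hypergeometric P is upper-tail: P(X >= k) for k tissue-specific genes
    (specificity >= ``threshold``) in the subset, K in the population,
    drawing n = |subset| from N = |population|. The Welch t-test compares
    the subset's abundance in ``tissue`` against the whole population.
    """
    population = list(spec.indices.index)
    subset = [g for g in subset_genes if g in spec.indices.index]
    if not subset:
        return TissueEnrichmentResult(
            float("nan"), 0, 0, 0, len(population), float("nan"), float("nan"),
            float("nan"), float("nan"), "empty subset after filtering",
        )
    specific = spec.indices[tissue] >= threshold
    N = len(population)
    K = int(specific.sum())
    n = len(subset)
    k = int(specific.loc[subset].sum())
    p_hyper = float(stats.hypergeom.sf(k - 1, N, K, n))
    x = expr.loc[subset, tissue].to_numpy(float)
    y = expr.loc[population, tissue].to_numpy(float)
    t_res = stats.ttest_ind(x, y, equal_var=False)
    return TissueEnrichmentResult(
        p_hyper, k, K, n, N,
        float(t_res.statistic), float(t_res.pvalue),
        float(x.mean()), float(y.mean()),
    )


def assign_peaks_to_genes(
    peaks: pd.DataFrame, genes: pd.DataFrame, flank: int = 3000
) -> pd.DataFrame:
    """Keep peaks overlapping any gene span extended by ``flank`` on each side.

    Returns the peak rows with an added ``gene_ids`` column (comma-joined).
    ``peaks`` needs chrom/start/end; ``genes`` needs gene_id/chrom/start/end.
    """
    g = genes.copy()
    g["start"] = (g["start"] - flank).clip(lower=0)
    g["end"] = g["end"] + flank
    pairs = overlap_pairs(
        peaks[["chrom", "start", "end"]], g[["chrom", "start", "end"]]
    )
    if len(pairs) == 0:
        out = peaks.iloc[0:0].copy()
        out["gene_ids"] = pd.Series(dtype=str)
        return out
    gene_ids = genes["gene_id"].to_numpy()
    assigned = (
        pairs.assign(gene=gene_ids[pairs["t"]])
        .groupby("q")["gene"]
        .agg(lambda s: ",".join(sorted(set(s))))
    )
    out = peaks.reset_index(drop=True).loc[assigned.index].copy()
    out["gene_ids"] = assigned
    return out.reset_index(drop=True)


def atac_overlap_test(
    outliers: SVCatalog,
    background: SVCatalog,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 3000,
) -> EnrichmentResult:
    """Fisher test: do outlier SVs overlap gene-assigned ATAC peaks more often?

    Peaks are first restricted to those within ``flank`` bases of a gene
    span; each SV is then scored for >=1 bp overlap with any retained peak.
    Rows of the 2x2 are (outlier, background), columns (peak-overlapping,
    not).
    """
    assigned = assign_peaks_to_genes(peaks, genes, flank)
    if len(assigned) == 0:
        raise ConfigurationError("no gene-assigned peaks; test skipped")

    def n_hits(cat: SVCatalog) -> int:
        if len(cat) == 0:
            return 0
        pairs = overlap_pairs(
            cat.df[["chrom", "start", "end"]],
            assigned[["chrom", "start", "end"]],
        )
        return int(pairs["q"].nunique())

    a = n_hits(outliers)
    b = n_hits(background)
    t = np.array(
        [[a, len(outliers) - a], [b, len(background) - b]], dtype=int
    )
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return EnrichmentResult(t, float(odds), float(p), "atac_outlier_vs_background")


def link_svs_to_genes(
    catalog: SVCatalog, genes: pd.DataFrame, flank: int = 5000
) -> pd.DataFrame:
    """Link every SV to genes within ``flank`` bases of the gene span.

    Returns a frame (sv_id, gene_id, distance); distance is 0 for body
    overlap, otherwise the gap between SV and gene span.
    """
    g = genes.copy()
    g["w_start"] = (g["start"] - flank).clip(lower=0)
    g["w_end"] = g["end"] + flank
    pairs = overlap_pairs(
        catalog.df[["chrom", "start", "end"]],
        g[["chrom", "start", "end"]].assign(
            start=g["w_start"], end=g["w_end"]
        ),
    )
    if len(pairs) == 0:
        return pd.DataFrame(columns=["sv_id", "gene_id", "distance"])
    sv = catalog.df.reset_index(drop=True)
    s_start = sv["start"].to_numpy()[pairs["q"]]
    s_end = sv["end"].to_numpy()[pairs["q"]]
    g_start = genes["start"].to_numpy()[pairs["t"]]
    g_end = genes["end"].to_numpy()[pairs["t"]]
    gap = np.maximum(
        0, np.maximum(g_start - s_end, s_start - g_end)
    )
    return pd.DataFrame(
        {
            "sv_id": sv["id"].to_numpy()[pairs["q"]],
            "gene_id": genes["gene_id"].to_numpy()[pairs["t"]],
            "distance": gap,
        }
    ).sort_values(["sv_id", "gene_id"], ignore_index=True)
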