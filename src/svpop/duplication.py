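"""SV overlap with whole-genome-duplication ohnologs vs singleton genes.

Genes retained in duplicate after an ancestral whole-genome duplication
("ohnologs") provide functional redundancy and may tolerate structural
variation better than singleton genes. This module tests whether SVs
preferentially overlap ohnologs (Fisher exact on a gene-level 2x2 table),
whether SV-overlapped ohnolog pairs are less co-expressed than random pairs
(resampling null on the median Spearman correlation across tissues), and
whether SV-overlapped copies are expressed lower than their partners
(Wilcoxon rank-sum on summed log10 abundance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from svpop.errors import ConfigurationError
from svpop.intervals import overlap_pairs
from svpop.svset import SVCatalog

GENE_COLUMNS = ["gene_id", "chrom", "start", "end"]


@dataclass
class OhnologTable:
    """Duplicate gene pairs and singletons, with gene intervals.

    ``genes`` has columns gene_id, chrom, start, end; ``pairs`` has columns
    gene_a, gene_b; ``singletons`` is a list of gene ids. A gene belongs to
    at most one pair and never to both a pair and the singleton list.
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame
    singletons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        paired = list(self.pairs["gene_a"]) + list(self.pairs["gene_b"])
        if len(set(paired)) != len(paired):
            raise ConfigurationError("a gene appears in more than one pair")
        if set(paired) & set(self.singletons):
            raise ConfigurationError("gene is both paired and singleton")
        known = set(self.genes["gene_id"])
        missing = (set(paired) | set(self.singletons)) - known
        if missing:
            raise ConfigurationError(
                f"{len(missing)} pair/singleton gene(s) lack intervals"
            )

    @property
    def paired_genes(self) -> list:
        return list(self.pairs["gene_a"]) + list(self.pairs["gene_b"])

    @classmethod
    def read_tsv(cls, path) -> "OhnologTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        genes = df[GENE_COLUMNS]
        pair_rows = df[df["partner"].notna() & (df["role"] == "a")]
        pairs = pd.DataFrame(
            {"gene_a": pair_rows["gene_id"], "gene_b": pair_rows["partner"]}
        ).reset_index(drop=True)
        singles = list(df.loc[df["partner"].isna(), "gene_id"])
        return cls(genes, pairs, singles)

    def write_tsv(self, path) -> None:
        partner = {}
        role = {}
        for a, b in zip(self.pairs["gene_a"], self.pairs["gene_b"]):
            partner[a], partner[b] = b, a
            role[a], role[b] = "a", "b"
        df = self.genes.copy()
        df["partner"] = df["gene_id"].map(partner)
        df["role"] = df["gene_id"].map(role)
        df.to_csv(path, sep="\t", index=False)


def gene_overlap_flags(
    catalog: SVCatalog, genes: pd.DataFrame, svtype: str | None = None
) -> pd.Series:
    """Per-gene boolean: does >=1 SV (optionally of one type) overlap the gene?

    ``genes`` needs columns gene_id, chrom, start, end. Overlap means >=1
    shared base (half-open intervals).
    """
    df = catalog.df
    if svtype is not None:
        df = df[df["svtype"] == svtype]
    flags = pd.Series(False, index=list(genes["gene_id"]), name="sv_overlap")
    if len(df) and len(genes):
        pairs = overlap_pairs(genes[["chrom", "start", "end"]], df)
        hit_genes = genes["gene_id"].to_numpy()[pairs["q"].unique()]
        flags.loc[hit_genes] = True
    return flags


@dataclass
class EnrichmentResult:
    """2x2 exact-test result with margins conserved by construction."""

    table: np.ndarray  # rows: classes, cols: (overlapped, not)
    odds_ratio: float
    pvalue: float
    label: str

    @property
    def proportions(self) -> tuple[float, float]:
        t = self.table
        return (
            t[0, 0] / t[0].sum() if t[0].sum() else float("nan"),
            t[1, 0] / t[1].sum() if t[1].sum() else float("nan"),
        )


def ohnolog_enrichment(
    flags: pd.Series, table: OhnologTable, label: str = "ohnolog_vs_singleton"
) -> EnrichmentResult:
    """Fisher exact test of SV overlap in ohnolog vs singleton genes.

    ``flags`` is the per-gene overlap indicator from
    :func:`gene_overlap_flags`; each flagged gene must appear in the table.
    Rows of the 2x2 are (ohnolog, singleton), columns (overlapped, not).
    """
    paired = [g for g in table.paired_genes if g in flags.index]
    singles = [g for g in table.singletons if g in flags.index]
    if len(paired) < len(set(table.paired_genes)) or len(singles) < len(
        set(table.singletons)
    ):
        raise ConfigurationError("flags must cover every gene in the table")
    o_hit = int(flags.loc[paired].sum())
    s_hit = int(flags.loc[singles].sum())
    t = np.array(
        [[o_hit, len(paired) - o_hit], [s_hit, len(singles) - s_hit]], dtype=int
    )
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        warnings.warn("ohnolog_enrichment: zero margin, OR undefined", stacklevel=2)
        return EnrichmentResult(t, float("nan"), 1.0, label)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return EnrichmentResult(t, float(odds), float(p), label)


def _pair_spearman(expr: pd.DataFrame, pairs: pd.DataFrame) -> pd.Series:
    """Spearman correlation across tissues for each (gene_a, gene_b) pair.

    Pairs with a constant-expression member are dropped with a warning.
    """
    if expr.shape[1] < 3:
        raise ConfigurationError("need >=3 tissues for correlation")
    vals = {}
    dropped = 0
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        xa = expr.loc[a].to_numpy(float)
        xb = expr.loc[b].to_numpy(float)
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            dropped += 1
            continue
        rho, _ = stats.spearmanr(xa, xb)
        vals[(a, b)] = rho
    if dropped:
        warnings.warn(
            f"{dropped} pair(s) with constant expression dropped", stacklevel=2
        )
    return pd.Series(vals, dtype=float)


def expression_correlation_resample(
    table: OhnologTable,
    expr: pd.DataFrame,
    sv_pairs: pd.DataFrame,
    n_resample: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Is the median co-expression of SV-overlapped pairs unusually low?

    Computes the median across-tissue Spearman correlation of ``sv_pairs``
    (a subset of ``table.pairs``) and compares it with medians of
    ``n_resample`` randomly sampled pair sets of the same size drawn from
    all pairs. Returns (observed median, empirical P), where P is the
    proportion of resampled medians STRICTLY LOWER than the observed one.
    Deterministic given ``seed``.
    """
    if len(sv_pairs) < 2:
        raise ConfigurationError("need >=2 SV-overlapped pairs")
    all_rho = _pair_spearman(expr, table.pairs)
    keys = [
        (a, b)
        for a, b in zip(sv_pairs["gene_a"], sv_pairs["gene_b"])
        if (a, b) in all_rho.index
    ]
    observed = float(np.median(all_rho.loc[keys]))
    rng = np.random.default_rng(seed)
    rho_values = all_rho.to_numpy()
    k = len(keys)
    medians = np.empty(n_resample)
    for i in range(n_resample):
        medians[i] = np.median(rng.choice(rho_values, size=k, replace=False))
    p = float((medians < observed).sum() / n_resample)
    return observed, p


@dataclass
class LevelTestResult:
    name: str
    statistic: float
    pvalue: float
    n1: int
    n2: int
    skipped_reason: str | None = None


def _sum_log10(expr: pd.DataFrame, pseudocount: float = 1e-3) -> pd.Series:
    return np.log10(expr + pseudocount).sum(axis=1)


def _ranksum(x, y, name: str) -> LevelTestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        return LevelTestResult(name, float("nan"), float("nan"), len(x), len(y),
                               "empty group")
    method = "exact" if max(len(x), len(y)) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return LevelTestResult(name, float(res.statistic), float(res.pvalue),
                           len(x), len(y))


def expression_level_tests(
    table: OhnologTable,
    expr: pd.DataFrame,
    flags: pd.Series,
    pseudocount: float = 1e-3,
) -> list[LevelTestResult]:
    """Wilcoxon rank-sum tests of expression level vs SV overlap.

    Gene score = sum over tissues of log10(abundance + pseudocount).

    (i) ``overlapped_vs_partner``: within pairs where exactly one copy is
        overlapped, the overlapped copies' scores vs their partners'.
    (ii) ``overlapped_pairs_vs_clean_pairs``: per-pair mean score for pairs
        with >=1 overlapped member vs pairs with none.

    Exact P when both groups have <=10 observations, normal approximation
    otherwise.
    """
    score = _sum_log10(expr, pseudocount)
    a_flag = flags.loc[table.pairs["gene_a"]].to_numpy()
    b_flag = flags.loc[table.pairs["gene_b"]].to_numpy()
    discordant = a_flag != b_flag
    hit_gene = np.where(a_flag, table.pairs["gene_a"], table.pairs["gene_b"])
    other_gene = np.where(a_flag, table.pairs["gene_b"], table.pairs["gene_a"])
    res_i = _ranksum(
        score.loc[hit_gene[discordant]],
        score.loc[other_gene[discordant]],
        "overlapped_vs_partner",
    )
    pair_mean = (
        score.loc[table.pairs["gene_a"]].to_numpy()
        + score.loc[table.pairs["gene_b"]].to_numpy()
    ) / 2
    any_hit = a_flag | b_flag
    res_ii = _ranksum(
        pair_mean[any_hit], pair_mean[~any_hit], "overlapped_pairs_vs_clean_pairs"
    )
    return [res_i, res_ii]
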