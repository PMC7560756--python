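"""Synthetic cohorts, SV catalogs, coverage, curation labels, amplicon
pileups, ohnolog tables and expression matrices with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline can be calibrated end-to-end:

* a cohort of wild populations split over two diverged lineages plus a
  latitudinal cline, and a farmed group derived from one wild population,
  with allele frequencies drawn from the Balding-Nichols model
  (population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around the
  ancestral frequency p, so the expected Weir-Cockerham theta between two
  groups at divergence F is approximately F);
* planted outlier SVs whose farmed-group allele frequency is shifted by a
  configurable delta;
* per-type SV size distributions (log-normal bodies) with a narrow uniform
  spike of deletion sizes in 1432-1436 bp mimicking an intact
  transposon-excision allele;
* region-dependent false-call probabilities for curation labels;
* read pileups over SV breakpoints with binomial allele sampling;
* ohnolog pairs with tunable across-tissue expression correlation and a
  multiplicative expression reduction for SV-overlapped copies.

Determinism: the single config seed is expanded into independent named
substreams (one per operation), so adding or re-running one stage never
perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from svpop.errors import ConfigurationError
from svpop.regions import CoverageProfile, RegionSet
from svpop.duplication import OhnologTable
from svpop.svset import SVCatalog, GenotypeMatrix, CATALOG_COLUMNS

#: tissue panel used for synthetic expression matrices
TISSUES = [
    "brain", "liver", "gill", "muscle", "spleen", "heart", "foregut",
    "pyloric_caeca", "pancreas", "skin", "kidney", "gonad", "eye",
    "nose", "fin",
]

# fixed stream ids for seed substreams; append only, never reorder
_STREAMS = {
    "cohort": 1,
    "catalog": 2,
    "coverage": 3,
    "curation": 4,
    "amplicon": 5,
    "ohnolog": 6,
    "expression": 7,
    "peaks": 8,
}


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic study.

    Defaults mirror the study design the analyses target: a farmed group of
    34 against 257 wild individuals, wild populations on two lineages with
    a latitudinal cline, deletion-dominated SV catalog with a 1432-1436 bp
    size spike, false-call probability 0.992 inside complex regions and
    0.85 outside, mean coverage ~8x with >=100x complex regions, and a
    15-tissue expression panel.
    """

    # cohort
    n_wild: int = 257
    n_farmed: int = 34
    n_populations: int = 4
    latitudes: tuple = (58.0, 62.0, 66.0, 70.0)
    divergence_F: float = 0.05
    within_lineage_F_fraction: float = 0.2  # pop-level F = fraction * divergence_F
    cline_strength: float = 0.3  # logit shift across the latitude range
    farm_source_pop: int = 0
    farm_drift_F: float = 0.02
    missing_rate: float = 0.01
    # SV catalog
    n_sv: dict = field(
        default_factory=lambda: {"DEL": 2000, "DUP": 180, "INV": 35}
    )
    spike_fraction: float = 0.0074  # of deletions, uniform in [1432, 1436]
    size_lognorm: dict = field(
        default_factory=lambda: {
            "DEL": (6.2, 1.5),
            "DUP": (7.5, 1.8),
            "INV": (10.0, 1.7),
        }
    )
    min_sv_size: int = 100
    genome: tuple = (("chr1", 5_000_000), ("chr2", 4_000_000), ("chr3", 3_000_000))
    # outliers
    n_planted_outliers: int = 50
    outlier_freq_shift: float = 0.3
    # coverage
    window_size: int = 1000
    depth_mean: float = 8.1
    depth_high: float = 150.0
    n_high_regions: int = 3
    high_region_windows: int = 2
    high_region_n_samples: int = 120
    # curation
    fdr_complex: float = 0.992
    fdr_normal: float = 0.85
    maybe_fraction: float = 0.2  # of false calls labeled 'maybe' (rest 'no')
    # amplicons
    n_amplicons: int = 876
    amplicon_mean_cov: float = 200.0
    amplicon_error_rate: float = 0.02
    amplicon_dropout_rate: float = 0.05
    amplicon_unassigned_rate: float = 0.05
    # ohnologs / expression
    n_ohnolog_pairs: int = 500
    n_singletons: int = 400
    n_tissues: int = 15
    expr_rho: float = 0.6
    expr_rho_sv: float | None = None  # default expr_rho - 0.1
    expr_sv_effect: float = 0.7
    # seed
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fractions = {
            "spike_fraction": self.spike_fraction,
            "divergence_F": self.divergence_F,
            "farm_drift_F": self.farm_drift_F,
            "missing_rate": self.missing_rate,
            "outlier_freq_shift": self.outlier_freq_shift,
            "fdr_complex": self.fdr_complex,
            "fdr_normal": self.fdr_normal,
            "maybe_fraction": self.maybe_fraction,
            "amplicon_error_rate": self.amplicon_error_rate,
            "amplicon_dropout_rate": self.amplicon_dropout_rate,
            "amplicon_unassigned_rate": self.amplicon_unassigned_rate,
            "expr_sv_effect": self.expr_sv_effect,
        }
        for name, v in fractions.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        counts = {
            "n_wild": self.n_wild,
            "n_farmed": self.n_farmed,
            "n_populations": self.n_populations,
            "n_planted_outliers": self.n_planted_outliers,
            "n_ohnolog_pairs": self.n_ohnolog_pairs,
            "n_singletons": self.n_singletons,
            "n_amplicons": self.n_amplicons,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.n_populations > 0 and len(self.latitudes) != self.n_populations:
            raise ConfigurationError(
                "latitudes must have one entry per population"
            )
        if any(not math.isfinite(x) for x in self.latitudes):
            raise ConfigurationError("latitudes must be finite")
        for t, n in self.n_sv.items():
            if n < 0:
                raise ConfigurationError(f"n_sv[{t}] must be >= 0")
        for chrom, length in self.genome:
            if length <= 0:
                raise ConfigurationError(f"genome length for {chrom} must be > 0")
        if self.window_size <= 0:
            raise ConfigurationError("window_size must be > 0")
        if self.n_tissues < 3:
            raise ConfigurationError("need >= 3 tissues (correlation undefined)")

    @property
    def rho_sv(self) -> float:
        if self.expr_rho_sv is not None:
            return self.expr_rho_sv
        return max(self.expr_rho - 0.1, -1.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        d["latitudes"] = list(self.latitudes)
        d["size_lognorm"] = {k: list(v) for k, v in self.size_lognorm.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "genome" in d:
            d["genome"] = tuple((c, int(ln)) for c, ln in d["genome"])
        if "latitudes" in d:
            d["latitudes"] = tuple(float(x) for x in d["latitudes"])
        if "size_lognorm" in d:
            d["size_lognorm"] = {
                k: tuple(float(x) for x in v) for k, v in d["size_lognorm"].items()
            }
        return cls(**d)


@dataclass
class TruthTable:
    """Planted ground truth: per-SV flags/frequencies and per-gene status."""

    sv: pd.DataFrame  # sv_id, svtype, is_true_call, is_planted_outlier, freqs
    genes: pd.DataFrame | None = None  # gene_id, is_ohnolog, sv_overlap


def sv_ids(config: SimConfig) -> pd.DataFrame:
    """Deterministic SV id/type manifest shared by catalog and cohort."""
    rows = []
    for svtype in ("DEL", "DUP", "INV"):
        for i in range(config.n_sv.get(svtype, 0)):
            rows.append({"sv_id": f"{svtype.lower()}_{i:05d}", "svtype": svtype})
    return pd.DataFrame(rows, columns=["sv_id", "svtype"])


def _balding_nichols(rng, p: np.ndarray, F: float) -> np.ndarray:
    """Population frequencies drawn around ancestral p at divergence F."""
    if F <= 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(a, b)


def simulate_cohort(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthTable]:
    """Genotypes, sample metadata, and planted truth for the study cohort.

    Wild populations are split over two lineages at ``divergence_F``; within
    a lineage, populations diverge at ``within_lineage_F_fraction *
    divergence_F`` and receive a logit-scale latitudinal shift. The farmed
    group drifts from wild population ``farm_source_pop`` and, at
    ``n_planted_outliers`` randomly chosen SVs, its allele frequency is
    shifted up by ``outlier_freq_shift``. Genotypes are Hardy-Weinberg
    draws; a ``missing_rate`` fraction is masked. Deterministic per seed.
    """
    rng = _rng(config, "cohort")
    manifest = sv_ids(config)
    n_sv = len(manifest)
    n_pop = config.n_populations

    # samples
    pop_sizes = [
        config.n_wild // n_pop + (1 if i < config.n_wild % n_pop else 0)
        for i in range(n_pop)
    ] if n_pop else []
    rows = []
    for i, size in enumerate(pop_sizes):
        lineage = "lineage1" if i < (n_pop + 1) // 2 else "lineage2"
        for j in range(size):
            rows.append(
                {
                    "sample_id": f"wild_p{i}_{j:03d}",
                    "population": f"pop{i}",
                    "origin": "wild",
                    "lineage": lineage,
                    "latitude": config.latitudes[i],
                }
            )
    for j in range(config.n_farmed):
        rows.append(
            {
                "sample_id": f"farmed_{j:03d}",
                "population": "farmed",
                "origin": "farmed",
                "lineage": "lineage1" if config.farm_source_pop < (n_pop + 1) // 2
                else "lineage2",
                "latitude": float("nan"),
            }
        )
    samples = pd.DataFrame(
        rows,
        columns=["sample_id", "population", "origin", "lineage", "latitude"],
    )

    # allele frequencies
    p_anc = rng.uniform(0.05, 0.95, size=n_sv)
    p_lineage = {
        lin: _balding_nichols(rng, p_anc, config.divergence_F)
        for lin in ("lineage1", "lineage2")
    }
    F_pop = config.divergence_F * config.within_lineage_F_fraction
    lats = np.asarray(config.latitudes, dtype=float)
    if n_pop > 1 and np.ptp(lats) > 0:
        z = (lats - lats.mean()) / np.ptp(lats)
    else:
        z = np.zeros(n_pop)
    pop_freq = {}
    for i in range(n_pop):
        lin = "lineage1" if i < (n_pop + 1) // 2 else "lineage2"
        f = np.clip(_balding_nichols(rng, p_lineage[lin], F_pop), 1e-9, 1 - 1e-9)
        logit = np.log(f / (1 - f)) + config.cline_strength * z[i]
        pop_freq[f"pop{i}"] = 1 / (1 + np.exp(-logit))
    if config.n_farmed:
        src = pop_freq[f"pop{config.farm_source_pop}"] if n_pop else p_anc
        pop_freq["farmed"] = _balding_nichols(rng, src, config.farm_drift_F)

    # planted outliers: frequency shift in the farmed group
    outlier_idx = np.array([], dtype=int)
    if config.n_planted_outliers and config.n_farmed and n_sv:
        k = min(config.n_planted_outliers, n_sv)
        outlier_idx = rng.choice(n_sv, size=k, replace=False)
        shifted = pop_freq["farmed"].copy()
        shifted[outlier_idx] = np.clip(
            shifted[outlier_idx] + config.outlier_freq_shift, 0.01, 0.99
        )
        pop_freq["farmed"] = shifted

    # Hardy-Weinberg genotypes
    codes = np.zeros((n_sv, len(samples)), dtype=np.int8)
    for pop, sub in samples.groupby("population", sort=False):
        cols = sub.index.to_numpy()
        freq = pop_freq[pop]
        codes[:, cols] = rng.binomial(
            2, freq[:, None], size=(n_sv, len(cols))
        ).astype(np.int8)
    if config.missing_rate > 0 and codes.size:
        mask = rng.random(codes.shape) < config.missing_rate
        codes[mask] = -1

    gm = GenotypeMatrix(codes, list(manifest["sv_id"]), list(samples["sample_id"]))
    truth_sv = manifest.copy()
    truth_sv["is_true_call"] = True
    truth_sv["is_planted_outlier"] = False
    if outlier_idx.size:
        truth_sv.loc[outlier_idx, "is_planted_outlier"] = True
    for pop, freq in pop_freq.items():
        truth_sv[f"freq_{pop}"] = freq
    return gm, samples, TruthTable(sv=truth_sv)


def simulate_sv_catalog(config: SimConfig) -> SVCatalog:
    """SV records with per-type log-normal sizes and the deletion size spike.

    A ``spike_fraction`` of deletions get sizes uniform in [1432, 1436];
    the rest follow ``min_sv_size + LogNormal(mu, sigma)`` per type. SVs
    longer than their chromosome are rejected and resampled. Positions are
    uniform within chromosome bounds; chromosomes are chosen with
    probability proportional to length.
    """
    rng = _rng(config, "catalog")
    manifest = sv_ids(config)
    chroms = [c for c, _ in config.genome]
    lengths = np.array([ln for _, ln in config.genome], dtype=float)
    probs = lengths / lengths.sum()
    max_len = int(lengths.max())
    rows = []
    for svtype, sub in manifest.groupby("svtype", sort=False):
        mu, sigma = config.size_lognorm[svtype]
        n = len(sub)
        sizes = config.min_sv_size + np.floor(
            rng.lognormal(mu, sigma, size=n)
        ).astype(int)
        if svtype == "DEL" and config.spike_fraction > 0:
            spike = rng.random(n) < config.spike_fraction
            sizes[spike] = rng.integers(1432, 1437, size=int(spike.sum()))
        n_resampled = 0
        while (sizes >= max_len).any():
            bad = sizes >= max_len
            n_resampled += int(bad.sum())
            sizes[bad] = config.min_sv_size + np.floor(
                rng.lognormal(mu, sigma, size=int(bad.sum()))
            ).astype(int)
        if n_resampled:
            import logging

            logging.getLogger(__name__).info(
                "simulate_sv_catalog: resampled %d %s size(s) exceeding "
                "chromosome bounds", n_resampled, svtype,
            )
        for sv_id, size in zip(sub["sv_id"], sizes):
            while True:
                ci = rng.choice(len(chroms), p=probs)
                if size < lengths[ci]:
                    break
            start = int(rng.integers(0, int(lengths[ci]) - size))
            rows.append(
                {
                    "id": sv_id,
                    "chrom": chroms[ci],
                    "start": start,
                    "end": start + int(size),
                    "svtype": svtype,
                    "size": int(size),
                }
            )
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    return SVCatalog(df).sorted()


def simulate_coverage(config: SimConfig) -> CoverageProfile:
    """Per-sample window depths with planted high-depth complex regions.

    Baseline depth is Poisson(``depth_mean``) per window and sample.
    ``n_high_regions`` runs of ``high_region_windows`` consecutive windows
    get depth >= ``depth_high`` in ``high_region_n_samples`` random samples;
    the planted intervals are recorded in ``truth_regions``.
    """
    for chrom, length in config.genome:
        if config.window_size > length:
            raise ConfigurationError(
                f"window_size {config.window_size} exceeds {chrom} length"
            )
    rng = _rng(config, "coverage")
    n_samples = config.n_wild + config.n_farmed
    win_rows = []
    for chrom, length in config.genome:
        for s in range(0, length, config.window_size):
            win_rows.append(
                {"chrom": chrom, "start": s, "end": min(s + config.window_size, length)}
            )
    windows = pd.DataFrame(win_rows)
    depth = rng.poisson(config.depth_mean, size=(len(windows), n_samples)).astype(
        float
    )
    truth = []
    if config.n_high_regions:
        starts = rng.choice(
            len(windows) - config.high_region_windows,
            size=config.n_high_regions,
            replace=False,
        )
        for w0 in starts:
            w1 = w0 + config.high_region_windows
            # clamp the run to one chromosome
            chrom = windows["chrom"].iloc[w0]
            w1 = min(w1, int((windows["chrom"] == chrom).to_numpy().nonzero()[0][-1]) + 1)
            cols = rng.choice(
                n_samples,
                size=min(config.high_region_n_samples, n_samples),
                replace=False,
            )
            depth[w0:w1][:, cols] = config.depth_high
            truth.append(
                (chrom, int(windows["start"].iloc[w0]), int(windows["end"].iloc[w1 - 1]))
            )
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    return CoverageProfile(
        windows,
        depth,
        sample_ids,
        truth_regions=RegionSet.from_intervals(truth, label="planted_high_depth"),
    )


def simulate_curation_labels(
    catalog: SVCatalog,
    regions: RegionSet,
    config: SimConfig,
    truth: TruthTable | None = None,
) -> pd.DataFrame:
    """Curation labels with region-dependent false-call probability.

    Calls overlapping ``regions`` are false with probability
    ``fdr_complex``; other calls with ``fdr_normal``. False calls are
    labeled 'no' or 'maybe' (``maybe_fraction``), true calls 'yes'. Planted
    outlier SVs (from ``truth``) are kept true so the outlier scan's ground
    truth stays intact. Columns: call_id, label, region_class, is_true_call.
    """
    from svpop.intervals import overlaps_merged

    rng = _rng(config, "curation")
    df = catalog.df
    in_region = (
        overlaps_merged(df[["chrom", "start", "end"]], regions.df)
        if len(regions)
        else np.zeros(len(df), dtype=bool)
    )
    p_false = np.where(in_region, config.fdr_complex, config.fdr_normal)
    is_false = rng.random(len(df)) < p_false
    if truth is not None:
        planted = set(
            truth.sv.loc[truth.sv["is_planted_outlier"], "sv_id"]
        )
        is_false &= ~df["id"].isin(planted).to_numpy()
    label = np.where(
        is_false,
        np.where(rng.random(len(df)) < config.maybe_fraction, "maybe", "no"),
        "yes",
    )
    return pd.DataFrame(
        {
            "call_id": df["id"].to_numpy(),
            "label": label,
            "region_class": np.where(in_region, "complex", "normal"),
            "is_true_call": ~is_false,
        }
    )


def simulate_amplicon_pileups(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    pairs: list[tuple] | None = None,
) -> pd.DataFrame:
    """Read pileups over SV breakpoints for selected (SV, sample) pairs.

    Coverage is Poisson(``amplicon_mean_cov``) with an
    ``amplicon_dropout_rate`` fraction of failed PCRs (<50 reads); a
    fraction of reads is unassignable to either allele; assignable reads
    support the SV allele with probability err, 0.5 or 1-err for genotypes
    0/0, 0/1, 1/1 (err = ``amplicon_error_rate``). The pipeline's call
    (``called_gt``) is the true genotype. Pairs with missing genotypes are
    skipped.
    """
    rng = _rng(config, "amplicon")
    if pairs is None:
        n = min(config.n_amplicons, genotypes.n_sv * genotypes.n_samples)
        flat = rng.choice(
            genotypes.n_sv * genotypes.n_samples, size=n, replace=False
        )
        pairs = [
            (genotypes.sv_ids[i // genotypes.n_samples],
             genotypes.sample_ids[i % genotypes.n_samples])
            for i in flat
        ]
    sv_index = {s: i for i, s in enumerate(genotypes.sv_ids)}
    sm_index = {s: i for i, s in enumerate(genotypes.sample_ids)}
    err = config.amplicon_error_rate
    rows = []
    for sv_id, sample_id in pairs:
        g = int(genotypes.codes[sv_index[sv_id], sm_index[sample_id]])
        if g < 0:
            continue
        if rng.random() < config.amplicon_dropout_rate:
            n_total = int(rng.integers(5, 50))
        else:
            n_total = int(rng.poisson(config.amplicon_mean_cov))
        n_unassigned = rng.binomial(n_total, config.amplicon_unassigned_rate)
        assignable = n_total - n_unassigned
        f_alt = {0: err, 1: 0.5, 2: 1.0 - err}[g]
        n_alt = int(rng.binomial(assignable, f_alt))
        rows.append(
            {
                "sv_id": sv_id,
                "sample_id": sample_id,
                "n_total": n_total,
                "n_alt": n_alt,
                "n_ref": assignable - n_alt,
                "called_gt": {0: "0/0", 1: "0/1", 2: "1/1"}[g],
                "true_gt": {0: "0/0", 1: "0/1", 2: "1/1"}[g],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sv_id", "sample_id", "n_total", "n_alt", "n_ref",
                 "called_gt", "true_gt"],
    )


def simulate_ohnolog_table(config: SimConfig) -> OhnologTable:
    """Gene intervals for ohnolog pairs and singletons, placed uniformly."""
    rng = _rng(config, "ohnolog")
    n_genes = 2 * config.n_ohnolog_pairs + config.n_singletons
    chroms = [c for c, _ in config.genome]
    lengths = np.array([ln for _, ln in config.genome], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    for i in range(n_genes):
        size = int(np.clip(rng.lognormal(9.0, 0.6), 500, None))
        while True:
            ci = rng.choice(len(chroms), p=probs)
            if size < lengths[ci]:
                break
        start = int(rng.integers(0, int(lengths[ci]) - size))
        rows.append(
            {
                "gene_id": f"gene_{i:05d}",
                "chrom": chroms[ci],
                "start": start,
                "end": start + size,
            }
        )
    genes = pd.DataFrame(rows)
    pairs = pd.DataFrame(
        {
            "gene_a": [f"gene_{2 * i:05d}" for i in range(config.n_ohnolog_pairs)],
            "gene_b": [f"gene_{2 * i + 1:05d}" for i in range(config.n_ohnolog_pairs)],
        }
    )
    singles = [
        f"gene_{i:05d}"
        for i in range(2 * config.n_ohnolog_pairs, n_genes)
    ]
    return OhnologTable(genes, pairs, singles)


def simulate_expression(
    ohnologs: OhnologTable,
    overlapped_genes,
    config: SimConfig,
) -> pd.DataFrame:
    """Gene x tissue abundance with tunable within-pair correlation.

    Pair members share a latent tissue profile drawn from a bivariate
    normal whose Pearson correlation is chosen so the population Spearman
    correlation equals ``expr_rho`` (``rho_sv`` for pairs with an
    SV-overlapped member); abundance is exp-transformed, keeping values
    positive and the Spearman target intact. SV-overlapped copies are
    multiplied by ``expr_sv_effect``. ``overlapped_genes`` is an iterable
    of gene ids.
    """
    if config.n_tissues < 3:
        raise ConfigurationError("need >= 3 tissues")
    rng = _rng(config, "expression")
    tissues = (TISSUES * ((config.n_tissues // len(TISSUES)) + 1))[: config.n_tissues]
    tissues = [
        t if tissues.count(t) == 1 else f"{t}_{k}"
        for k, t in enumerate(tissues)
    ]
    overlapped = set(overlapped_genes)
    T = config.n_tissues

    def pearson_for_spearman(rho_s: float) -> float:
        return float(np.clip(2 * np.sin(np.pi * rho_s / 6), -1.0, 1.0))

    data = {}
    for a, b in zip(ohnologs.pairs["gene_a"], ohnologs.pairs["gene_b"]):
        rho_s = config.rho_sv if (a in overlapped or b in overlapped) else config.expr_rho
        r = pearson_for_spearman(rho_s)
        z0 = rng.normal(size=T)
        z1 = r * z0 + np.sqrt(max(1 - r * r, 0.0)) * rng.normal(size=T)
        mu = rng.normal(2.0, 1.0)
        data[a] = np.exp(mu + z0)
        data[b] = np.exp(mu + z1)
    for g in ohnologs.singletons:
        mu = rng.normal(2.0, 1.0)
        data[g] = np.exp(mu + rng.normal(size=T))
    expr = pd.DataFrame(data).T
    expr.columns = tissues
    expr.index.name = "gene_id"
    if config.expr_sv_effect != 1.0 and overlapped:
        hit = [g for g in expr.index if g in overlapped]
        expr.loc[hit] = expr.loc[hit] * config.expr_sv_effect
    return expr


def simulate_peaks(
    genes: pd.DataFrame,
    config: SimConfig,
    fraction: float = 0.2,
    peak_size: int = 400,
    offset_max: int = 2000,
) -> pd.DataFrame:
    """Open-chromatin peaks near a random fraction of genes (plumbing)."""
    rng = _rng(config, "peaks")
    rows = []
    for rec in genes.itertuples(index=False):
        if rng.random() >= fraction:
            continue
        offset = int(rng.integers(-offset_max, offset_max))
        start = max(0, rec.start + offset)
        rows.append({"chrom": rec.chrom, "start": start, "end": start + peak_size})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
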