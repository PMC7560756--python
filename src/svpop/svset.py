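"""SV catalog and genotype data model, VCF I/O, redundancy collapse, dosage
recoding and curation-based FDR estimation.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based VCF convention happens only at the VCF boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from svpop.errors import ConfigurationError, VcfRecordError

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV")

#: genotype codes in :class:`GenotypeMatrix`: alt-allele dosage, -1 = missing
MISSING = -1

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_CODES = {v: k for k, v in _GT_STRINGS.items()}

CATALOG_COLUMNS = ["id", "chrom", "start", "end", "svtype", "size"]


@dataclass
class SVCatalog:
    """Table of SV records: id, chrom, start, end (0-based half-open),
    svtype in {DEL, DUP, INV} and size = end - start."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"catalog missing columns: {missing}")
        if len(df):
            if not (df["start"] < df["end"]).all():
                raise ConfigurationError("catalog has records with start >= end")
            bad = set(df["svtype"]) - set(SV_TYPES)
            if bad:
                raise ConfigurationError(f"unknown svtype(s): {sorted(bad)}")
            if not (df["size"] == df["end"] - df["start"]).all():
                raise ConfigurationError("size != end - start")
            if df["id"].duplicated().any():
                raise ConfigurationError("duplicate SV ids")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "SVCatalog":
        return SVCatalog(
            self.df.sort_values(["chrom", "start", "end", "id"], kind="mergesort")
        )

    def subset(self, ids) -> "SVCatalog":
        ids = set(ids)
        return SVCatalog(self.df[self.df["id"].isin(ids)])

    def type_counts(self) -> pd.Series:
        return self.df["svtype"].value_counts()


@dataclass
class GenotypeMatrix:
    """SV x sample diploid genotypes coded as alt-allele dosage.

    ``codes`` is an int8 array with entries 0 (0/0), 1 (0/1), 2 (1/1) or
    -1 (missing).
    """

    codes: np.ndarray
    sv_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ConfigurationError("genotype codes must be 2-D (SV x sample)")
        if self.codes.shape != (len(self.sv_ids), len(self.sample_ids)):
            raise ConfigurationError(
                "genotype matrix shape does not match sv/sample ids"
            )
        valid = np.isin(self.codes, (-1, 0, 1, 2))
        if not valid.all():
            raise ConfigurationError("genotype codes outside {-1,0,1,2}")

    @property
    def n_sv(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def row(self, sv_id) -> np.ndarray:
        return self.codes[self.sv_ids.index(sv_id)]

    def subset_svs(self, ids) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sv_ids)}
        keep = [order[i] for i in ids]
        return GenotypeMatrix(
            self.codes[keep], [self.sv_ids[k] for k in keep], list(self.sample_ids)
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=svpop
{contigs}##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    path,
    catalog: SVCatalog,
    genotypes: GenotypeMatrix | None = None,
    genome: list[tuple[str, int]] | None = None,
) -> None:
    """Write the catalog (and genotypes, if given) as a VCF 4.2 text file.

    Internal 0-based half-open [start, end) becomes POS = start + 1 and
    INFO/END = end (1-based inclusive end == half-open end).
    """
    if genotypes is not None and genotypes.sv_ids != list(catalog.df["id"]):
        raise ConfigurationError("genotype sv ids do not match catalog order")
    if genome is None:
        genome = [
            (c, int(e))
            for c, e in catalog.df.groupby("chrom")["end"].max().items()
        ]
    contigs = "".join(
        f"##contig=<ID={c},length={ln}>\n" for c, ln in genome
    )
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    samples = genotypes.sample_ids if genotypes is not None else []
    if samples:
        cols += "\tFORMAT\t" + "\t".join(str(s) for s in samples)
    lines = [_VCF_HEADER.format(contigs=contigs) + cols]
    for i, rec in enumerate(catalog.df.itertuples(index=False)):
        svlen = -rec.size if rec.svtype == "DEL" else rec.size
        row = (
            f"{rec.chrom}\t{rec.start + 1}\t{rec.id}\tN\t<{rec.svtype}>\t.\t.\t"
            f"SVTYPE={rec.svtype};END={rec.end};SVLEN={svlen}"
        )
        if samples:
            gts = "\t".join(_GT_STRINGS[int(g)] for g in genotypes.codes[i])
            row += "\tGT\t" + gts
        lines.append(row)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> tuple[SVCatalog, GenotypeMatrix | None]:
    """Read SV records and GT genotypes from a VCF with SVTYPE/END INFO tags.

    Records missing SVTYPE or END raise :class:`VcfRecordError` naming the
    record; records with an SVTYPE outside {DEL, DUP, INV} are skipped with
    a warning and counted in the log.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    codes_rows = []
    n_skipped = 0
    for i, v in enumerate(vcf, start=1):
        svtype = v.INFO.get("SVTYPE")
        end = v.INFO.get("END")
        if svtype is None:
            raise VcfRecordError(f"record {i} (POS {v.POS}): missing SVTYPE")
        if end is None:
            raise VcfRecordError(f"record {i} (POS {v.POS}): missing END")
        if svtype not in SV_TYPES:
            warnings.warn(
                f"record {i}: unknown SVTYPE {svtype!r}, skipped", stacklevel=2
            )
            n_skipped += 1
            continue
        start = v.POS - 1
        end = int(end)
        rows.append(
            {
                "id": v.ID if v.ID else f"sv_{i}",
                "chrom": v.CHROM,
                "start": start,
                "end": end,
                "svtype": svtype,
                "size": end - start,
            }
        )
        if samples:
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = v.gt_types
            codes_rows.append(
                np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
            )
    if n_skipped:
        logger.info("read_vcf: skipped %d records with unknown SVTYPE", n_skipped)
    catalog = SVCatalog(pd.DataFrame(rows, columns=CATALOG_COLUMNS))
    gm = None
    if samples:
        codes = (
            np.vstack(codes_rows).astype(np.int8)
            if codes_rows
            else np.zeros((0, len(samples)), dtype=np.int8)
        )
        gm = GenotypeMatrix(codes, list(catalog.df["id"]), samples)
    return catalog, gm


# ---------------------------------------------------------------------------
# Redundancy collapse
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def collapse_redundant(
    catalog: SVCatalog, reciprocal: float = 0.9
) -> tuple[SVCatalog, list]:
    """Remove redundant same-type SVs at a reciprocal-overlap threshold.

    Two SVs of the same type are redundant iff their overlap length is
    >= ``reciprocal`` times the size of EACH. Redundancy groups are the
    connected components of this relation; from each group the record with
    the smallest (start, end, id) is kept. Returns (kept catalog, list of
    removed ids).
    """
    if not (0 < reciprocal <= 1):
        raise ConfigurationError("reciprocal must be in (0, 1]")
    df = catalog.sorted().df
    n = len(df)
    uf = _UnionFind(n)
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    sizes = df["size"].to_numpy()
    for _, idx in df.groupby(["chrom", "svtype"]).groups.items():
        idx = np.asarray(idx)
        # sorted by start within group (df is globally sorted)
        for a_pos in range(len(idx)):
            i = idx[a_pos]
            for b_pos in range(a_pos + 1, len(idx)):
                j = idx[b_pos]
                if starts[j] >= ends[i]:
                    break  # no further overlap possible with i
                ov = min(ends[i], ends[j]) - max(starts[i], starts[j])
                if ov >= reciprocal * sizes[i] and ov >= reciprocal * sizes[j]:
                    uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    keep_rows = []
    removed: list = []
    for members in groups.values():
        best = min(
            members,
            key=lambda k: (starts[k], ends[k], str(df["id"].iloc[k])),
        )
        keep_rows.append(best)
        removed.extend(df["id"].iloc[k] for k in members if k != best)
    kept = SVCatalog(df.iloc[sorted(keep_rows)])
    if removed:
        logger.info("collapse_redundant: removed %d redundant SVs", len(removed))
    return kept, removed


# ---------------------------------------------------------------------------
# Dosage recoding
# ---------------------------------------------------------------------------


def recode_dosage(
    matrix: GenotypeMatrix, missing_policy: str = "mean"
) -> pd.DataFrame:
    """Recode genotypes to dosage 0/1/2 as an SV x sample float frame.

    ``missing_policy="mean"`` (default) imputes missing entries with the
    per-SV mean of the observed dosages; ``"drop"`` drops SVs containing any
    missing genotype. SVs with all genotypes missing are excluded with a
    warning under either policy.
    """
    if missing_policy not in ("mean", "drop"):
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    codes = matrix.codes.astype(float)
    obs = codes >= 0
    all_missing = ~obs.any(axis=1)
    if all_missing.any():
        dropped = [matrix.sv_ids[i] for i in np.flatnonzero(all_missing)]
        warnings.warn(
            f"recode_dosage: {len(dropped)} SV(s) with all genotypes missing "
            "excluded",
            stacklevel=2,
        )
    if missing_policy == "drop":
        keep = obs.all(axis=1)
    else:
        keep = ~all_missing
        with np.errstate(invalid="ignore"):
            means = np.where(
                obs.sum(axis=1) > 0,
                np.where(obs, codes, 0).sum(axis=1) / np.maximum(obs.sum(axis=1), 1),
                np.nan,
            )
        codes = np.where(obs, codes, means[:, None])
    out = pd.DataFrame(
        codes[keep],
        index=[matrix.sv_ids[i] for i in np.flatnonzero(keep)],
        columns=matrix.sample_ids,
    )
    out.index.name = "sv_id"
    return out


# ---------------------------------------------------------------------------
# Curation FDR
# ---------------------------------------------------------------------------

LOW_CONFIDENCE_LABELS = ("no", "maybe")


@dataclass
class FdrReport:
    """FDR for one stratum of curated calls: fraction judged low-confidence.

    Only 'yes' labels count as high-confidence; 'no' and 'maybe' are
    low-confidence. ``fdr`` is NaN (flagged undefined) for empty strata.
    """

    stratum: str
    n_total: int
    n_low_confidence: int

    @property
    def fdr(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return self.n_low_confidence / self.n_total


def estimate_fdr(
    labels: pd.DataFrame, strata: str | None = "region_class"
) -> list[FdrReport]:
    """Curation FDR per stratum plus overall.

    ``labels`` needs columns ``call_id``, ``label`` (yes/no/maybe) and, if
    ``strata`` is a column name, that column. The overall report is always
    last; stratum totals partition the overall total.
    """
    if len(labels) == 0:
        raise ConfigurationError("estimate_fdr: labels are empty")
    bad = set(labels["label"].str.lower()) - {"yes", "no", "maybe"}
    if bad:
        raise ConfigurationError(f"unknown curation labels: {sorted(bad)}")
    low = labels["label"].str.lower().isin(LOW_CONFIDENCE_LABELS)
    reports = []
    if strata is not None and strata in labels.columns:
        for name, sub in labels.groupby(strata, sort=True, dropna=False):
            reports.append(
                FdrReport(str(name), len(sub), int(low.loc[sub.index].sum()))
            )
    reports.append(FdrReport("overall", len(labels), int(low.sum())))
    return reports
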