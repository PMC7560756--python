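"""Coverage-derived complex regions, assembly gaps, and SV exclusion.

High-depth "complex" regions — typically collapsed duplicated sequence left
by delayed rediploidization after whole-genome duplication — attract false
SV calls. The rule implemented here flags a window when at least
``sample_threshold`` individuals show mean depth >= ``depth_threshold``
(default: >=100x in >=100 individuals), merges flagged windows within
``merge_gap`` bases, and excludes SV calls sharing >=1 bp with the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from svpop.errors import ConfigurationError
from svpop.intervals import INTERVAL_COLUMNS, merge_frame, overlaps_merged
from svpop.svset import SVCatalog


@dataclass
class RegionSet:
    """Sorted, merged, non-overlapping genomic intervals (0-based half-open)."""

    df: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        self.df = merge_frame(self.df)

    @classmethod
    def empty(cls, label: str = "") -> "RegionSet":
        return cls(pd.DataFrame(columns=INTERVAL_COLUMNS), label)

    @classmethod
    def from_intervals(cls, intervals, label: str = "") -> "RegionSet":
        """Build from an iterable of (chrom, start, end)."""
        df = pd.DataFrame(list(intervals), columns=INTERVAL_COLUMNS)
        return cls(df, label)

    @classmethod
    def read_bed(cls, path, label: str = "") -> "RegionSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=INTERVAL_COLUMNS,
            comment="#",
            dtype={"chrom": str},
        )
        return cls(df, label)

    def write_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def total_bases(self) -> int:
        if len(self.df) == 0:
            return 0
        return int((self.df["end"] - self.df["start"]).sum())


@dataclass
class CoverageProfile:
    """Mean sequencing depth per sample on a window grid tiling the genome.

    ``depth`` is a (n_windows, n_samples) array aligned with ``windows``
    rows (chrom, start, end) and ``sample_ids``.
    """

    windows: pd.DataFrame
    depth: np.ndarray
    sample_ids: list = field(default_factory=list)
    truth_regions: RegionSet | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.windows), len(self.sample_ids)):
            raise ConfigurationError("coverage depth shape mismatch")
        if (self.depth < 0).any():
            raise ConfigurationError("negative depths")

    def write_tsv(self, path) -> None:
        out = pd.concat(
            [
                self.windows.reset_index(drop=True),
                pd.DataFrame(self.depth, columns=self.sample_ids),
            ],
            axis=1,
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CoverageProfile":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        samples = [c for c in df.columns if c not in INTERVAL_COLUMNS]
        return cls(df[INTERVAL_COLUMNS], df[samples].to_numpy(float), samples)


def find_high_depth_regions(
    coverage: CoverageProfile,
    depth_threshold: float = 100,
    sample_threshold: int = 100,
    merge_gap: int = 100,
) -> RegionSet:
    """Windows with >= depth_threshold coverage in >= sample_threshold samples,
    merged when separated by <= merge_gap bases on the same chromosome."""
    if depth_threshold <= 0 or sample_threshold <= 0:
        raise ConfigurationError("thresholds must be positive")
    if sample_threshold > len(coverage.sample_ids):
        raise ConfigurationError(
            f"sample_threshold {sample_threshold} exceeds the "
            f"{len(coverage.sample_ids)} samples in the profile"
        )
    n_qualifying = (coverage.depth >= depth_threshold).sum(axis=1)
    flagged = coverage.windows[n_qualifying >= sample_threshold]
    merged = merge_frame(flagged, gap=merge_gap)
    return RegionSet(merged, label="high_depth")


def merge_regions(a: RegionSet, b: RegionSet, label: str = "") -> RegionSet:
    """Union of two region sets with overlapping/abutting intervals coalesced."""
    df = pd.concat([a.df, b.df], ignore_index=True)
    return RegionSet(df, label or f"{a.label}+{b.label}")


def exclude_overlapping(
    catalog: SVCatalog, regions: RegionSet
) -> tuple[SVCatalog, SVCatalog]:
    """Partition the catalog into (kept, excluded) by >=1 bp region overlap."""
    if len(catalog) == 0:
        return catalog, SVCatalog(catalog.df.iloc[0:0])
    hits = overlaps_merged(catalog.df[INTERVAL_COLUMNS], regions.df)
    return SVCatalog(catalog.df[~hits]), SVCatalog(catalog.df[hits])
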