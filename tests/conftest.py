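import numpy as np
import pandas as pd
import pytest

from svpop.simulate import SimConfig
from svpop.svset import SVCatalog, CATALOG_COLUMNS


@pytest.fixture
def small_config():
    """A small two-population cohort used across unit tests."""
    return SimConfig(
        n_wild=40,
        n_farmed=10,
        n_populations=2,
        latitudes=(60.0, 66.0),
        n_sv={"DEL": 100, "DUP": 20, "INV": 5},
        n_planted_outliers=5,
        seed=7,
    )


def make_catalog(records):
    """Catalog from (id, chrom, start, end, svtype) tuples."""
    rows = [
        {"id": i, "chrom": c, "start": s, "end": e, "svtype": t, "size": e - s}
        for i, c, s, e, t in records
    ]
    return SVCatalog(pd.DataFrame(rows, columns=CATALOG_COLUMNS))


def random_catalog(rng, n, chrom_len=10_000, n_chroms=2, max_size=400):
    """Random small catalog for brute-force oracle comparisons."""
    rows = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        size = int(rng.integers(50, max_size))
        start = int(rng.integers(0, chrom_len - size))
        svtype = rng.choice(["DEL", "DUP", "INV"], p=[0.8, 0.15, 0.05])
        rows.append(
            {"id": f"sv{i:04d}", "chrom": chrom, "start": start,
             "end": start + size, "svtype": svtype, "size": size}
        )
    return SVCatalog(pd.DataFrame(rows, columns=CATALOG_COLUMNS))
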