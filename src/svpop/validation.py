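"""Amplicon-pileup genotype classification and concordance reporting.

Long-read amplicon sequencing over SV breakpoints yields, per (SV, sample)
pair, a read pileup with counts supporting the SV allele and the reference
allele. Classification follows fixed thresholds: pileups under ``min_cov``
total reads are failed PCRs; among allele-assignable reads, an allele
fraction above ``hom_frac`` calls the corresponding homozygote, and at
least ``het_frac`` on both alleles calls a heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from svpop.errors import ConfigurationError

FAIL = "FAIL"

#: reasons attached to FAIL classifications
REASON_LOW_COVERAGE = "low_coverage"
REASON_NO_ASSIGNABLE = "no_assignable_reads"


def classify_amplicon(
    n_total: int,
    n_alt: int,
    n_ref: int,
    min_cov: int = 50,
    hom_frac: float = 0.9,
    het_frac: float = 0.1,
) -> tuple[str, str | None]:
    """Classify one pileup into 0/0, 0/1, 1/1 or FAIL.

    Returns ``(genotype, fail_reason)``; the reason is None unless the
    genotype is FAIL. Reads assignable to neither allele count toward the
    coverage gate but not the allele fractions. The rule order is: coverage
    gate, then homozygote checks (strict >), then the heterozygote check
    (>= on both fractions); with ``hom_frac + het_frac = 1`` exactly one
    genotype always applies.
    """
    if min(n_total, n_alt, n_ref) < 0 or n_alt + n_ref > n_total:
        raise ConfigurationError("invalid pileup counts")
    if n_total < min_cov:
        return FAIL, REASON_LOW_COVERAGE
    assignable = n_alt + n_ref
    if assignable == 0:
        return FAIL, REASON_NO_ASSIGNABLE
    # compare integer counts against threshold * assignable with a tolerance
    # so exact boundaries (e.g. 90/100 with hom_frac 0.9) resolve per the
    # stated rules: strict > for homozygotes, >= for the heterozygote
    tol = 1e-9
    if n_alt > hom_frac * assignable + tol:
        return "1/1", None
    if n_ref > hom_frac * assignable + tol:
        return "0/0", None
    if n_alt >= het_frac * assignable - tol and n_ref >= het_frac * assignable - tol:
        return "0/1", None
    return FAIL, "ambiguous_fraction"  # unreachable when hom+het fracs = 1


def classify_pileups(
    pileups: pd.DataFrame,
    min_cov: int = 50,
    hom_frac: float = 0.9,
    het_frac: float = 0.1,
) -> pd.DataFrame:
    """Vector version: adds ``validated_gt`` and ``fail_reason`` columns.

    Expects columns n_total, n_alt, n_ref.
    """
    out = pileups.copy()
    res = [
        classify_amplicon(t, a, r, min_cov, hom_frac, het_frac)
        for t, a, r in zip(out["n_total"], out["n_alt"], out["n_ref"])
    ]
    out["validated_gt"] = [g for g, _ in res]
    out["fail_reason"] = [r for _, r in res]
    return out


@dataclass
class ConcordanceReport:
    """Agreement between pipeline calls and amplicon-validated genotypes.

    Presence concordance: both sides agree on whether >=1 SV allele is
    present. Genotype concordance: exact diploid genotype match. FAILed
    validations are excluded from all denominators.
    """

    per_type: pd.DataFrame  # rows per svtype + 'overall'

    def rate(self, svtype: str, kind: str = "presence") -> float:
        row = self.per_type.set_index("svtype").loc[svtype]
        return row[f"{kind}_rate"]


def _has_alt(gt: pd.Series) -> pd.Series:
    return gt.isin(["0/1", "1/1"])


def concordance_report(
    classified: pd.DataFrame, svtypes: pd.Series | None = None
) -> ConcordanceReport:
    """Build per-type and overall concordance rates.

    ``classified`` needs columns called_gt, validated_gt (the latter from
    :func:`classify_pileups`) and either an svtype column or an
    ``svtypes`` mapping (sv_id -> type). Rows with validated_gt == FAIL
    are dropped first. Empty input yields a report with zero counts and
    NaN (undefined) rates.
    """
    classified = classified.copy()
    if "svtype" not in classified.columns:
        if svtypes is None:
            raise ConfigurationError(
                "classified pileups need an svtype column or an svtypes mapping"
            )
        classified["svtype"] = classified["sv_id"].map(svtypes)
    ok = classified[classified["validated_gt"] != FAIL].copy()
    ok["presence_conc"] = _has_alt(ok["called_gt"]) == _has_alt(ok["validated_gt"])
    ok["genotype_conc"] = ok["called_gt"] == ok["validated_gt"]
    rows = []
    groups = list(ok.groupby("svtype", sort=True)) + [("overall", ok)]
    for name, sub in groups:
        n = len(sub)
        rows.append(
            {
                "svtype": name,
                "n_calls": n,
                "n_presence_concordant": int(sub["presence_conc"].sum()),
                "n_genotype_concordant": int(sub["genotype_conc"].sum()),
                "presence_rate": sub["presence_conc"].mean() if n else np.nan,
                "genotype_rate": sub["genotype_conc"].mean() if n else np.nan,
            }
        )
    return ConcordanceReport(pd.DataFrame(rows))
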