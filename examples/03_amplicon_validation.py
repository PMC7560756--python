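"""Validate SV genotypes with long-read amplicon pileups.

Pileups under 50 reads are failed PCRs; >90% allele support calls a
homozygote, >=10% support for both alleles a heterozygote. Concordance is
reported for SV presence/absence and for the exact genotype.
"""

from svpop import SimConfig, concordance_report, simulate_cohort
from svpop.simulate import simulate_amplicon_pileups, simulate_sv_catalog
from svpop.validation import classify_pileups

config = SimConfig(seed=3)
genotypes, _, _ = simulate_cohort(config)
catalog = simulate_sv_catalog(config)

pileups = simulate_amplicon_pileups(genotypes, config)
classified = classify_pileups(pileups, min_cov=50, hom_frac=0.9, het_frac=0.1)
n_fail = (classified["validated_gt"] == "FAIL").sum()
print(f"{len(classified)} amplicons, {n_fail} failed the coverage gate")

report = concordance_report(classified,
                            svtypes=catalog.df.set_index("id")["svtype"])
print(report.per_type.to_string(index=False, float_format="%.3f"))
# presence_rate: agreement on whether any SV allele is present;
# genotype_rate: exact diploid genotype match (always <= presence here).
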