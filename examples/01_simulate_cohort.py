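"""Generate a synthetic SV cohort and inspect its planted structure.

Builds a wild + farmed cohort with Balding-Nichols allele frequencies and
planted farmed-shifted outlier SVs, plus an SV catalog whose deletion sizes
carry the 1432-1436 bp spike, then prints what was planted.
"""

from svpop import SimConfig, simulate_cohort, simulate_sv_catalog

config = SimConfig(seed=1)
genotypes, samples, truth = simulate_cohort(config)
catalog = simulate_sv_catalog(config)

print(f"cohort: {genotypes.n_samples} samples x {genotypes.n_sv} SVs")
print(samples["origin"].value_counts().to_string())
print(f"\ncatalog type counts:\n{catalog.type_counts().to_string()}")

deletions = catalog.df[catalog.df["svtype"] == "DEL"]
spike = deletions["size"].between(1432, 1436).mean()
print(f"\nmean deletion size: {deletions['size'].mean():.0f} bp; "
      f"{spike:.2%} of deletions in the 1432-1436 bp spike")

planted = truth.sv["is_planted_outlier"].sum()
shift = (truth.sv["freq_farmed"] - truth.sv["freq_pop0"])
print(f"\n{planted} planted outlier SVs; their farmed-vs-source frequency "
      f"shift averages {shift[truth.sv['is_planted_outlier']].mean():.2f} "
      f"(vs {shift[~truth.sv['is_planted_outlier']].mean():+.3f} for null SVs)")
# The shift is what the F_ST outlier scan is expected to recover.
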