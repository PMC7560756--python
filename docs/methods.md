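# Methods

## Scope and data model

`svpop` analyses a catalog of structural variants (SVs: DEL, DUP, INV;
≥ 100 bp) with per-sample diploid genotypes, sample metadata (population,
wild/farmed origin, latitude), genomic region sets (assembly gaps,
high-depth regions, ATAC peaks), curation labels, amplicon pileups, an
ohnolog table (WGD-retained duplicate gene pairs plus singletons, with gene
intervals) and a gene × tissue expression matrix. Internally all
coordinates are 0-based half-open; conversions happen only at the VCF
(1-based POS/END) and BED boundaries. Genotypes are stored as alt-allele
dosage codes 0/1/2 with −1 for missing.

## Reliability filtering and FDR accounting

A coverage window is flagged *complex* when at least `sample_threshold`
(default 100) samples show mean depth ≥ `depth_threshold` (default 100×).
Flagged windows within `merge_gap` (default 100 bp, inclusive) are merged;
the result can be unioned with assembly gaps, and any SV sharing ≥ 1 bp
with the combined set is excluded. The window grid itself is configurable
(default 1 kb): the thresholds are fixed by the detection rule but the
granularity of the underlying depth summary is an implementation choice.

Curation assigns each call a label in {yes, no, maybe}; the empirical FDR
of a stratum is the fraction labeled no or maybe (only 'yes' calls are
retained downstream). An empty stratum reports FDR = NaN, never 0. Strata
partition the calls, so stratum totals always sum to the overall total.

Redundant calls are removed at 90% reciprocal overlap: two same-type SVs
are redundant iff their overlap is ≥ 0.9 × the size of each; redundancy
groups are connected components of that relation, and the member with the
smallest (start, end, id) is kept — a deterministic tie-break, since the
underlying rule does not prescribe which copy survives. Cross-type overlap
never collapses records: a DEL and a DUP at the same locus are distinct
alleles.

## Amplicon validation

A pileup with fewer than `min_cov` (50) total reads is a failed PCR.
Among allele-assignable reads (reads matching neither allele count toward
the coverage gate only), an allele fraction strictly above `hom_frac`
(0.9) calls the corresponding homozygote; otherwise ≥ `het_frac` (0.1)
support for both alleles calls a heterozygote. With hom_frac + het_frac = 1
exactly one class applies; boundary fractions (e.g. 90/100) resolve to the
heterozygote because the homozygote rule is strict. The 0/0 rule mirrors
the 1/1 rule — the reference-homozygote case follows by symmetry.
Concordance is reported per SV type and pooled, on two definitions:
presence/absence (both sides agree whether ≥ 1 SV allele is present) and
exact genotype. FAILed pileups are excluded from all denominators; whether
0/0 confirmations belong in the denominator is not externally fixed, and
they are included here under the presence/absence rule.

## Weir–Cockerham F_ST and the permutation scan

For two groups with sizes n₁, n₂ (non-missing individuals, removed
pairwise per SV), alt-allele frequencies p₁, p₂ and heterozygote
proportions h₁, h₂, the estimator computes the standard variance
components a (among groups), b (among individuals within groups) and
c (within individuals), and θ = a/(a+b+c). θ is undefined when
a+b+c = 0 — in practice, when no alternative allele segregates in the
union of the groups — and such SVs are flagged excluded rather than scored.
θ may be negative; it is capped by 1 only in the sense that fixed
differences attain exactly 1.

Significance: individuals are permuted into two groups of the original
sizes `n_perm` times (default 200) and θ recomputed for every SV. The
per-SV P is the fraction of permuted values **strictly greater** than the
observed θ (ties count as non-exceedances; a ≥ rule is available behind the
`strict` flag). A single genome-wide cutoff is the q-quantile (default
0.997) of the **pooled** null — all finite permuted θ across SVs — and an
outlier must satisfy both P < α (default 0.01) and θ above the cutoff.
Pooling is one reading of a per-scan scalar cutoff; a per-distribution
criterion would be an alternative, but pooling yields the single
comparable threshold the two-gate rule needs. The permutation stream is
seeded independently of the data-generating stream, so rerunning the scan
never perturbs the cohort.

With n_perm = 200, the smallest achievable P values are 0 and 0.005, so
P < 0.01 corresponds to at most one exceedance; under exchangeable labels
the per-SV probability of that event is ≈ 2/201 ≈ 0.00995, which is what
the calibration tests check. Because all SVs share one permutation set,
the realized fraction across SVs is over-dispersed relative to binomial —
the tests bracket it rather than pinning it.

PCA operates on the centered sample × SV dosage matrix (missing genotypes
imputed with the per-SV mean by default); constant SVs are dropped with a
warning. Scores are deterministic up to sign.

## Ohnolog (WGD) analyses

Enrichment is tested at the gene level: each gene is flagged if ≥ 1 SV
(optionally restricted by type) shares ≥ 1 bp with its interval, giving a
2×2 table {ohnolog, singleton} × {overlapped, not} with margins equal to
the gene totals, tested with Fisher's exact test (two-sided). Gene-level
units keep the margins well-defined when one SV overlaps several genes.

Co-expression: per-pair Spearman correlation across ≥ 3 tissues (average
ranks on ties; pairs with a constant member are dropped with a warning).
The observed statistic is the median over SV-overlapped pairs; the null is
the median of `n_resample` (default 1000) random same-size pair sets drawn
without replacement from all pairs; P is the proportion of null medians
strictly lower than the observed median (so P near 0 means unusually LOW
co-expression).

Expression level: gene score = Σ_t log10(abundance + pseudocount), with a
1e-3 pseudocount because log of zero must be handled and the choice is not
externally fixed. Two Wilcoxon rank-sum tests: (i) overlapped copies vs
their partners within discordant pairs, and (ii) pair-mean scores of
overlapped pairs vs untouched pairs — exact when both groups have ≤ 10
observations, normal approximation otherwise.

## Functional annotation

Tissue specificity of gene g in tissue t is CPM(g,t) / Σ_t CPM(g,t) — the
normalized form, bounded in [0,1] and summing to 1 per gene, which is the
form compatible with a ≥ 0.5 threshold. Genes with total CPM < 1 are
filtered before any specificity test and never divide by zero. The
enrichment of a gene subset is an upper-tail hypergeometric P(X ≥ k) on the
count of specific genes (index ≥ threshold), against the filtered
transcriptome as population, plus a Welch (unequal-variance) two-sample
t-test on the focal tissue's abundance. ATAC peaks are assigned to genes
when they overlap the gene span ± 3000 bp; SV classes (outlier vs
background) are then compared on ≥ 1 bp overlap with any gene-assigned
peak by Fisher's exact test. SV→gene links use a 5 kb flank and carry
distance 0 for body overlap, else the gap length.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses target, and they are not tuned per test.

* **Cohort**: 257 wild individuals split over `n_populations` (default 4)
  populations on two lineages, plus 34 farmed individuals derived from one
  wild population. Allele frequencies follow the Balding–Nichols model:
  given ancestral frequency p ~ U(0.05, 0.95) and divergence F, a
  descendant frequency is Beta(p(1−F)/F, (1−p)(1−F)/F), so the expected
  Weir–Cockerham θ between two groups at divergence F is ≈ F — the
  closed-form link that makes divergence a recoverable parameter. Within a
  lineage, populations diverge at a configurable fraction (default 0.2) of
  the lineage-level F and receive a logit-scale latitudinal shift
  (`cline_strength`, default 0.3 across the latitude range) emulating the
  cline wild cohorts show. The farmed group drifts from its source
  population at `farm_drift_F` (default 0.02, a few generations of
  domestication) and, at `n_planted_outliers` SVs (default 50), its allele
  frequency is shifted up by `outlier_freq_shift` (default 0.3) and
  clipped to [0.01, 0.99]. Genotypes are Hardy–Weinberg binomial draws;
  1% are masked missing by default.
* **Catalog**: per-type sizes are `100 + LogNormal(μ, σ)` with defaults
  (6.2, 1.5) for DEL, (7.5, 1.8) for DUP and (10.0, 1.7) for INV — chosen
  to reproduce the observed ordering and rough scale of the three size
  distributions (deletions ~1.5 kb on average, duplications ~8 kb,
  inversions ~100 kb, all heavy-tailed). A `spike_fraction` (default
  0.0074, the observed share) of deletions is drawn uniformly in
  1432–1436 bp, mimicking a polymorphic intact DNA transposon. Default SV
  counts (2000/180/35) keep the catalog's type proportions at roughly
  1/7 of the real catalog for desk-scale runs. Positions are uniform;
  oversized draws are rejected and resampled with a log message.
* **Coverage**: Poisson(8.1) per window and sample, with planted runs of
  windows at depth 150 in 120 samples — positives the ≥100×/≥100 rule must
  find; the planted intervals are recorded as truth.
* **Curation**: calls are false with probability `fdr_complex` (0.992)
  inside the region set and `fdr_normal` (0.85) outside — the two
  published strata — and false calls are labeled no/maybe (80/20). Planted
  outliers are kept true so downstream truth stays intact. Curators are
  emulated as perfect (the published inter-curator agreement on kept calls
  was total), so the labels measure the planted false-call process, not
  curator noise.
* **Amplicons**: coverage Poisson(200) with a 5% failed-PCR fraction below
  50 reads, 5% unassignable reads, and binomial allele sampling at
  fractions {err, 0.5, 1−err} (err = 0.02) per genotype. The pipeline call
  equals the true genotype, so any discordance measures the classifier.
* **Expression**: pair members share a latent tissue profile
  z₁ = r·z₀ + √(1−r²)·ε with r = 2·sin(π·ρ_s/6), so the *population*
  Spearman correlation equals the target ρ_s (`expr_rho`, default 0.6;
  `expr_rho_sv`, default ρ−0.1, for SV-overlapped pairs) and survives the
  exp transform to positive abundances. SV-overlapped copies are
  multiplied by `expr_sv_effect` (default 0.7). A multiplicative effect
  cannot change a rank correlation, which is why the correlation of
  overlapped pairs has its own knob rather than being a side effect of the
  level reduction.
* **Seeding**: one config seed is expanded into fixed named substreams
  (cohort, catalog, coverage, curation, amplicon, ohnolog, expression,
  peaks), so adding or rerunning a stage never changes another stage's
  draws, and identical configs are bit-identical across runs.

### What the generator does not emulate

No read-level sequence, alignment or SV-caller error model (false calls
appear only through the curation-label process); no linkage disequilibrium
between SVs (genotypes are independent across loci given the frequencies);
no shared genomic placement between the SV catalog and the genotype
process (positions and frequencies are independent); genes are placed
uniformly rather than in clusters; expression noise is log-normal without
tissue-specific programs beyond the planted brain biases tests construct.
Passing calibration therefore shows the estimators are correct and
well-calibrated under the stated models — not that real cohorts meet those
models.

## Problem sizes and numerical conventions

Calibration tests and the acceptance script use 2000 SVs × 291 samples ×
200 permutations (the scan is vectorized over SVs and permutations and
completes in under a second), 2000 ohnolog pairs × 15 tissues, and 20,000
curation labels — sizes chosen so each Monte-Carlo tolerance is a small
multiple of the corresponding sampling error. Tolerances: θ against the
independent variance-component oracle at 1e-10; mean θ vs planted F at
±0.02 (2000 SVs); median Spearman vs planted ρ at ±0.05; stratified FDR
within 4 binomial standard errors. Amplicon boundary cases compare integer
counts against threshold × assignable with a 1e-9 tolerance so exact
boundaries (90/100 at 0.9) follow the stated strict/≥ rules rather than
floating-point rounding. Degenerate inputs are contracts, not crashes:
empty strata report NaN FDR, all-missing SVs are dropped with a warning,
monomorphic SVs are flagged excluded, empty gene subsets and empty peak
assignments skip their tests with a reason.

## Known limitations

The scan supports exactly two groups (the farmed/wild contrast); r > 2
scans, admixture modeling and LD pruning are out of scope. The published
headline numbers that depend on the real cohort (total SV counts, the 584
outliers, the 0.103 cutoff, the enrichment P values) are not reproduction
targets at desk scale; the package reproduces the published *arithmetic*
(FDR and concordance from the printed counts, the permutation-P rule) and
the *calibration properties* of the methods on planted truth.
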