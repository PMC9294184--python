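# Methods

## Study design

Each simulated association study consists of `n_variants` independent
biallelic variants typed in `n_individuals` diploid individuals
(default 1,417). Per variant:

1. **Allele frequency.** The alternative-allele frequency *p* is drawn
   from the MAF spectrum (default uniform on (0.005, 0.5)) or taken
   from a user list. Frequencies are restricted to (0, 0.5] so the
   alternative allele is the minor one.
2. **Genotypes.** Individuals are independent draws from the
   Hardy–Weinberg trinomial ((1−p)², 2p(1−p), p²) — no linkage
   disequilibrium, no inbreeding, no population structure.
3. **Phenotype.** Quantitative phenotypes are `N(0, σ²)` in the null
   scenario and `N(G, σ²)` in the alternative (additive effect of one
   phenotype unit per alternative allele); σ defaults to 6.5, which
   puts the per-allele effect near 0.15 phenotypic SD and overall power
   in the 0.7–0.8 range at the default sample size. Binary phenotypes
   are the median split of the quantitative ones (values strictly above
   the sample median → 1; ties at the median, probability-zero for
   continuous draws, go to 0). A fresh phenotype vector is drawn for
   every variant, so per-variant tests are mutually independent and
   Monte-Carlo standard errors are plain binomial.
4. **Read counts.** See the count model below.
5. **Calling.** Genotypes are re-called from the counts by maximum
   posterior under the diploid binomial likelihood with a flat prior;
   GQ is the difference between the second-best and best phred-scaled
   normalised posteriors, capped at 99 (the standard VCF convention).
   Zero-coverage samples are missing calls with GQ 0.

All randomness flows from one master seed: per-variant substreams are
spawned from `SeedSequence(seed)`, so studies are byte-reproducible and
trivially parallelisable.

## Count model

`CountModel` generates per-sample (ref, alt) read counts given the true
genotype.

**Coverage.** The default law is gamma-Poisson: a per-variant
sequencing rate λ_v ~ Gamma(mean 22, SD 2.2) is drawn once per variant,
and per-sample depth is Poisson(λ_v). Marginally this is negative
binomial, but the hierarchy matters: the between-variant component (SD
2.2 reads) is what creates the spread of per-variant typical coverage
that coverage-stratified summaries bin on (realized per-variant mean
coverage quartiles land near 21/22/24 reads), while per-sample noise
stays Poisson. A plain per-sample negative binomial with mean 22 cannot
have SD 2.2 at all — its SD is at least √22 ≈ 4.7 — which is why the
coverage spread is modelled at the variant level. Per-sample `poisson`,
`negative_binomial` and `fixed` laws are also available; `fixed` at 0
exercises the zero-coverage/missing-data path.

**Alternative-read fraction.** Given depth *c* and genotype *g*, the
alternative count is beta-binomial: a per-sample fraction is drawn from
Beta(μ_g ν, (1−μ_g) ν) and alt ~ Binomial(c, fraction), with
μ = (ε, ½, 1−ε) for g = 0, 1, 2. Defaults: effective per-read error
ε = 0.05 and concentration ν = 80. Setting `overdispersion=None` gives
plain binomial counts.

**Caller misspecification is deliberate.** The caller always uses the
standard base-quality error model ε = 0.01 (phred 20), *not* the
generative ε. Real pipelines have exactly this structure: the caller's
likelihood reflects base qualities, while the counts it sees also carry
misalignment, mapping bias and library artifacts that the model does
not know about. The generative ε = 0.05 is therefore an *effective*
per-read error at variant positions, not a base-miscall rate. This
mismatch is what gives genotype calling a realistic error profile at
medium coverage; with a perfectly matched ε = 0.01 binomial model,
calling at 22× is >99.9% concordant, the called-genotype test becomes
indistinguishable from the oracle, and the comparison the package
exists to study degenerates. Because the per-read errors are
independent, they average out as depth grows — calling improves with
coverage and the ratio-vs-called power gap shrinks, the qualitative
trend the simulations are designed to exhibit. The mild beta-binomial
component (ν = 80) adds residual site/sample noise that does not fully
wash out, as seen in real resequencing data.

Users who possess empirical category-specific count distributions
(e.g. keyed by ref allele × alt allele × genotype) can supply them via
`CountModel.category_table`; matching categories are resampled jointly
from the table and the parametric law fills the rest.

## Association tests

All three arms place the genotype-side quantity on the response side
with the phenotype as the single covariate, and test the phenotype
coefficient (Wald, two-sided):

- **Proportional odds** (oracle and called arms): cumulative-logit
  model, maximised by damped Newton with an analytic gradient; the
  Hessian is a central finite difference of that gradient, and the
  Wald SE comes from the observed information at the optimum. When the
  covariate takes few distinct values (the binary-phenotype studies)
  observations are collapsed to weighted (level, value) cells, making
  each fit a few-parameter optimisation over ≤6 cells. With two
  observed response levels the model *is* binary logistic regression,
  and the implementation agrees with an independent logistic fit to
  1e-6 (and with a tightly-converged proportional-odds reference fit to
  ~1e-8 on three levels). Declared failures — fewer than two observed
  levels, non-convergence within 100 iterations, |β| > 50 (separation),
  or a non-positive-definite information matrix — yield a missing
  p-value.
- **Ratio regression**: OLS of alt/(ref+alt) on the phenotype with the
  slope *t*-test, algebraically identical to the Pearson-correlation
  *t*-test. Zero-coverage samples have an undefined ratio and are
  dropped pairwise; fewer than 3 complete pairs or a zero-variance side
  gives a missing p-value; an exact fit reports the smallest positive
  float rather than 0.

Rejection rates are always "proportion of **non-missing** p-values ≤
α" (α = 0.05 default), reported with their binomial Monte-Carlo SE.
Power differences between two methods on the same study use the paired
per-variant SE, which is considerably tighter than treating the two
rates as independent.

## Stratified summaries

Variants can be stratified by MAF (default bins ≤0.05, (0.05,0.1],
(0.1,0.25], >0.25 — the first bin is the rare-variant stratum of
interest), by per-variant mean coverage, or by per-variant mean GQ
(quartile bounds of the realized statistic by default, user bounds
otherwise). Intervals are left-open/right-closed except the lowest.
The per-variant statistic is the mean across samples; the median is one
line of user code away (pass the statistic column directly). Duplicate
quartile bounds (degenerate statistics) are collapsed rather than
raising.

## VCF interface

Reading and writing go through pysam. GT is parsed to 0/1/2 dosage
(phased or unphased), AD to (ref, alt), GQ capped at 99; absent fields
become missing values without dropping the site. Multiallelic sites
are carried with a flag and removed — never truncated to two alleles —
by `filter_complete_biallelic`, which keeps biallelic variants with
complete GT and AD in every sample and reports counts removed per
reason. Coordinates are 1-based inclusive throughout; region queries
are simple scans, so no tabix index is needed. LD between variants is
the squared Pearson correlation of dosage vectors over
pairwise-complete samples (composite LD; no phasing required).

## What the simulations do and do not show

The generator emulates: HWE genotype sampling across a MAF spectrum,
median-split binary phenotypes, depth heterogeneity between variants,
and calling noise from an error process the caller's likelihood does
not fully describe. It does not emulate: linkage disequilibrium
(variants are independent), population structure or relatedness,
indels/multiallelic sites, base-quality variation within a sample,
allele-specific bias structured by the actual ref/alt nucleotides, or
empirical genotype-quality distributions from any specific platform.
Conclusions supported by the simulations are therefore *qualitative* —
type-I error control of all three tests, the oracle ≥ ratio ≥ called
power ordering, and the growth of the ratio advantage as coverage,
genotype quality or allele frequency fall. Exact power values depend
on the MAF spectrum and on the empirical noise of a given pipeline and
should not be read off these defaults.

## Monte-Carlo sizes and numerical choices

The study-scale checks in `tests/test_acceptance.py` use 5,000 variants
× 1,417 individuals for the null and alternative benchmarks (binomial
MC SE ≈ 0.003 on a rate of 0.05), 2,000 variants per coverage
configuration (8, 15, 22, 40 reads) for the coverage trend, and a
dedicated 2,500-variant MAF ∈ (0.005, 0.05) study for the rare-variant
comparison — the rare stratum of a uniform-MAF study holds only ~9% of
its variants, too few for a stable stratum-level comparison. Trend
assertions allow two paired MC standard errors of slack per step.
Posterior ties in calling are broken toward the heterozygote, then the
lower genotype code; `stratify_variants` places boundary values in the
lower stratum; the Newton fit starts from empirical cumulative logits
with zero slope.

## Known limitations

- The proportional-odds fit targets the single-covariate case used
  here; there is no covariate adjustment, mixed-model correction or
  multiple-testing machinery.
- The ratio test treats the ratio as homoskedastic even though its
  sampling variance scales with 1/depth; a weighted or beta-regression
  variant might squeeze out more power at very uneven coverage.
- BCF and indexed region queries are out of scope; large compressed
  VCFs should be pre-sliced with standard tools.
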