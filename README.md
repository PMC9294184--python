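# adassoc

Genetic association tests usually regress on *called* genotypes. When
genotypes come from next-generation sequencing, calling throws away
information: a sample covered by 6 reads and a sample covered by 40
reads produce equally confident-looking 0/1/2 codes, and every miscall
enters the regression as if it were certain. `adassoc` implements and
evaluates the alternative of testing association directly on the
**allelic depths** — the ratio of alternative-allele reads to coverage
at each site — against the classical called-genotype analysis.

It is aimed at statistical geneticists who want to benchmark the two
approaches under controlled conditions, and at analysts who want to run
the count-based test on their own VCFs.

## The tests

For each variant, with phenotype *y* as the explanatory variable:

1. **Oracle** (simulated data only): proportional-odds regression
   `P(G ≤ k | y) = σ(θ_k − β y)` of the *true* genotype
   `G ∈ {0,1,2}` — the upper power bound.
2. **Called genotypes**: the same cumulative-logit model on genotypes
   called from read counts by maximum posterior under the diploid
   binomial likelihood `P(alt read | G) = ε, ½, 1−ε` with a flat prior
   (⅓ each), GATK-style GQ reporting.
3. **Alt-read ratio**: ordinary least squares
   `alt/(ref+alt) = α + β y + e`, two-sided *t*-test on β.

Both genotype-side quantities are the *response*; this reversed
direction keeps the three arms directly comparable. Significance is a
Wald test on β; degenerate fits (monomorphic response, separation,
non-convergence) report a missing p-value, and rejection rates always
use the non-missing count as denominator.

The simulation half of the package generates complete studies — HWE
genotypes from a MAF spectrum, phenotypes `N(G, σ²)` (alternative) or
`N(0, σ²)` (null) with optional median-split dichotomisation, and
read counts from a configurable coverage/error model — and summarises
type-I error and power, overall and stratified by MAF, coverage, or
genotype quality.

## Worked example

```python
from adassoc import SimConfig, simulate_study, run_scan, rejection_rate
from adassoc.evaluate import paired_power_gap

cfg = SimConfig(n_variants=400, scenario="alternative",
                phenotype_kind="binary", seed=7)
bundle = simulate_study(cfg)          # 1417 individuals, ~22x coverage
results = run_scan(bundle)            # all three tests per variant

for method in ("oracle_ordinal", "called_ordinal", "ratio_linear"):
    rr = rejection_rate(results[results.method == method]["pvalue"])
    print(f"{method:15s} power at alpha=0.05: {rr.proportion:.3f}")
gap, se = paired_power_gap(results)
print(f"ratio - called power gap: {gap:+.3f} (MC SE {se:.3f})")
```

prints

```
oracle_ordinal  power at alpha=0.05: 0.697
called_ordinal  power at alpha=0.05: 0.627
ratio_linear    power at alpha=0.05: 0.642
ratio - called power gap: +0.015 (MC SE 0.017)
```

The oracle bounds both feasible tests; the ratio test recovers part of
the power that genotype calling loses, and the gap widens at low
coverage and low minor allele frequency (see `docs/methods.md`). At
this small Monte-Carlo size (400 variants) the gap is within its own
standard error; the study-scale runs below use 5,000 variants.

The same scan runs on real data from the shell:

```sh
adassoc vcf-test --vcf cohort.vcf --pheno phenotypes.tsv --out assoc/
adassoc plot manhattan --results assoc/results.tsv --out manhattan.png
adassoc plot ld --vcf cohort.vcf --out ld.png
```

where `phenotypes.tsv` has columns `sample_id` and `phenotype`, and the
VCF carries GT/AD FORMAT fields. `adassoc simulate|call|test|evaluate`
expose the simulation pipeline; every command takes `--config` (flat
TOML, see `adassoc.cli`) and `--seed`.

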