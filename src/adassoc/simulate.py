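"""Simulation of NGS-based association studies.

The generative model, per variant:

1. a minor allele frequency is drawn (or supplied),
2. diploid genotypes (0/1/2 copies of the alternative allele) are drawn
   for ``n`` individuals under Hardy-Weinberg equilibrium,
3. a quantitative phenotype is assigned — N(0, sigma^2) in the null
   scenario, N(genotype, sigma^2) in the alternative — and optionally
   dichotomised by median split,
4. per-sample read counts at the variant position are drawn from a
   :class:`CountModel`: a coverage law for the total read depth and a
   per-genotype alternative-read fraction (binomial, or beta-binomial
   when overdispersed).

Each variant receives its own phenotype vector, so per-variant tests are
independent across variants by construction.  All randomness flows from
a single master seed through per-variant substreams, which makes study
bundles byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CoverageLaw",
    "CountModel",
    "SimConfig",
    "StudyBundle",
    "hwe_genotype_probs",
    "simulate_genotypes",
    "assign_phenotypes",
    "median_split",
    "simulate_counts",
    "simulate_study",
]

MISSING = -1  # genotype code for missing throughout the package

# Alternating ref/alt pairs used when exporting simulated variants; the
# default count model is allele-agnostic, so these are labels only.
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("A", "T"),
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("G", "A"), ("G", "C"), ("G", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class CoverageLaw:
    """Distribution of the per-sample total read depth at a variant.

    Kinds
    -----
    ``gamma_poisson`` (default)
        A per-variant sequencing rate lambda_v ~ Gamma(mean=``mean``,
        sd=``between_variant_sd``) is drawn once per variant; per-sample
        coverage is Poisson(lambda_v).  Marginally negative binomial.
        This separates the between-variant spread of typical coverage
        (which drives coverage-stratified summaries) from per-sample
        Poisson sampling noise.
    ``poisson``
        Per-sample coverage ~ Poisson(``mean``); no between-variant
        heterogeneity.
    ``negative_binomial``
        Per-sample coverage ~ NB with the given mean and ``sd``
        (requires ``sd**2 > mean``).
    ``fixed``
        Constant coverage ``mean`` (useful in tests; ``mean`` may be 0
        to exercise the missing-data path).
    """

    kind: str = "gamma_poisson"
    mean: float = 22.0
    between_variant_sd: float = 2.2
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"gamma_poisson", "poisson", "negative_binomial", "fixed"}:
            raise ValueError(f"unknown coverage law kind: {self.kind!r}")
        if self.mean < 0:
            raise ValueError("coverage mean must be nonnegative")
        if self.kind == "gamma_poisson" and self.between_variant_sd <= 0:
            raise ValueError("between_variant_sd must be positive")
        if self.kind == "negative_binomial":
            if self.sd is None or self.sd**2 <= self.mean:
                raise ValueError(
                    "negative_binomial coverage requires sd with sd^2 > mean"
                )
        if self.kind != "fixed" and self.mean == 0:
            raise ValueError("coverage mean must be positive for stochastic laws")

    def draw_rate(self, rng: np.random.Generator) -> float:
        """Draw the per-variant coverage rate (identical to ``mean`` for
        laws without between-variant heterogeneity)."""
        if self.kind == "gamma_poisson":
            shape = (self.mean / self.between_variant_sd) ** 2
            scale = self.between_variant_sd**2 / self.mean
            return float(rng.gamma(shape, scale))
        return float(self.mean)

    def draw(self, n: int, rng: np.random.Generator, rate: float | None = None) -> np.ndarray:
        """Draw ``n`` per-sample coverages (nonnegative integers)."""
        lam = self.mean if rate is None else rate
        if self.kind == "fixed":
            return np.full(n, int(round(self.mean)), dtype=np.int64)
        if self.kind in ("gamma_poisson", "poisson"):
            return rng.poisson(lam, size=n)
        # negative binomial: n_succ = m^2/(s^2-m), p = m/s^2
        var = self.sd**2  # type: ignore[operator]
        n_succ = self.mean**2 / (var - self.mean)
        p = self.mean / var
        return rng.negative_binomial(n_succ, p, size=n)


@dataclass(frozen=True)
class CountModel:
    """Generative model for (ref, alt) read counts given a genotype.

    Parameters
    ----------
    coverage_law
        Per-sample total read depth distribution.
    error_rate
        Per-read miscall probability epsilon in (0, 0.5).  The expected
        alternative-read fraction is epsilon for genotype 0 and
        1 - epsilon for genotype 2.
    het_alt_fraction
        Expected alternative-read fraction for heterozygotes (0.5 for
        unbiased sequencing).
    overdispersion
        Beta-binomial concentration nu (> 0); the per-sample alternative
        read fraction is Beta(mu*nu, (1-mu)*nu) around the genotype mean
        mu, capturing alignment and library noise beyond binomial read
        sampling.  ``None`` means plain binomial counts.
    category_table
        Optional mapping ``(ref_allele, alt_allele, genotype) ->
        (ref_counts, alt_counts)`` of empirical count pairs to resample
        jointly, for users who possess category-specific empirical
        distributions; it overrides the parametric law for the keys
        present.
    """

    coverage_law: CoverageLaw = field(default_factory=CoverageLaw)
    error_rate: float = 0.05
    het_alt_fraction: float = 0.5
    overdispersion: float | None = 80.0
    category_table: dict | None = None

    def __post_init__(self) -> None:
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        mu = self.alt_fractions()
        if not (mu[0] < mu[1] < mu[2]):
            raise ValueError("alt fractions must be ordered: mu0 < mu1 < mu2")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion concentration must be positive")

    def alt_fractions(self) -> np.ndarray:
        """Expected alt-read fraction per genotype, ``[mu0, mu1, mu2]``."""
        return np.array(
            [self.error_rate, self.het_alt_fraction, 1.0 - self.error_rate]
        )


def hwe_genotype_probs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2).

    ``maf`` is the alternative-allele frequency p, restricted to
    (0, 0.5] so that the alternative allele is the minor one.
    """
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    q = 1.0 - maf
    return (q * q, 2.0 * maf * q, maf * maf)


def simulate_genotypes(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent HWE genotypes (0/1/2 alt-allele copies)."""
    if n < 1:
        raise ValueError("n must be positive")
    probs = hwe_genotype_probs(maf)
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def assign_phenotypes(
    genotypes: np.ndarray,
    sigma: float,
    scenario: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign quantitative phenotypes given genotypes.

    Null scenario: i.i.d. N(0, sigma^2), independent of genotype.
    Alternative scenario: N(G_i, sigma^2) — the mean equals the number
    of alternative alleles carried, an additive genetic effect.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if scenario not in ("null", "alternative"):
        raise ValueError(f"scenario must be 'null' or 'alternative', got {scenario!r}")
    g = np.asarray(genotypes)
    if np.any(g < 0):
        raise ValueError("genotypes must be complete (no missing values)")
    mean = g.astype(float) if scenario == "alternative" else np.zeros(g.shape)
    return rng.normal(mean, sigma)


def median_split(y: np.ndarray) -> np.ndarray:
    """Dichotomise a quantitative phenotype at its sample median.

    Values strictly above the median become 1, values at or below it 0.
    For continuous phenotypes with even n this yields exactly n/2 ones.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("median split needs at least 2 values")
    return (y > np.median(y)).astype(np.int8)


def simulate_counts(
    genotypes: np.ndarray,
    model: CountModel,
    rng: np.random.Generator,
    *,
    rate: float | None = None,
    alleles: tuple[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ref_count, alt_count) per sample given true genotypes.

    Coverage c is drawn from the model's coverage law (optionally at a
    pre-drawn per-variant ``rate``), then ``alt ~ Binomial(c, mu_g)`` —
    or beta-binomial when the model is overdispersed — and
    ``ref = c - alt``.  With ``alleles`` given and a matching entry in
    ``model.category_table``, (ref, alt) pairs are resampled jointly
    from the stored empirical distribution instead.
    """
    g = np.asarray(genotypes)
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotypes must be in {0,1,2}")
    n = g.size

    if model.category_table is not None and alleles is not None:
        ref = np.empty(n, dtype=np.int64)
        alt = np.empty(n, dtype=np.int64)
        done = np.zeros(n, dtype=bool)
        for code in (0, 1, 2):
            key = (alleles[0], alleles[1], code)
            idx = np.flatnonzero(g == code)
            if idx.size == 0:
                continue
            if key in model.category_table:
                ref_pool, alt_pool = model.category_table[key]
                pick = rng.integers(0, len(ref_pool), size=idx.size)
                ref[idx] = np.asarray(ref_pool)[pick]
                alt[idx] = np.asarray(alt_pool)[pick]
                done[idx] = True
        if done.all():
            return ref, alt
        # fall through for genotype categories without an empirical entry
        rest = ~done
        ref_p, alt_p = _parametric_counts(g[rest], model, rng, rate)
        ref[rest] = ref_p
        alt[rest] = alt_p
        return ref, alt

    return _parametric_counts(g, model, rng, rate)


def _parametric_counts(
    g: np.ndarray,
    model: CountModel,
    rng: np.random.Generator,
    rate: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    n = g.size
    coverage = model.coverage_law.draw(n, rng, rate=rate)
    mu = model.alt_fractions()[g]
    if model.overdispersion is None:
        alt = rng.binomial(coverage, mu)
    else:
        nu = model.overdispersion
        frac = rng.beta(mu * nu, (1.0 - mu) * nu, size=n)
        alt = rng.binomial(coverage, frac)
    ref = coverage - alt
    return ref.astype(np.int64), alt.astype(np.int64)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated association study.

    Defaults mirror a medium-coverage human resequencing study:
    1417 individuals, coverage centred at 22 reads, phenotype SD 6.5
    (one alt allele shifts the quantitative phenotype mean by ~0.15 SD
    in the alternative scenario).
    """

    n_individuals: int = 1417
    n_variants: int = 1000
    maf_spec: Sequence[float] | tuple[str, float, float] = ("uniform", 0.005, 0.5)
    sigma: float = 6.5
    scenario: str = "null"
    phenotype_kind: str = "binary"
    count_model: CountModel = field(default_factory=CountModel)
    seed: int = 0
    chrom: str = "20"

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.scenario not in ("null", "alternative"):
            raise ValueError("scenario must be 'null' or 'alternative'")
        if self.phenotype_kind not in ("quantitative", "binary"):
            raise ValueError("phenotype_kind must be 'quantitative' or 'binary'")
        for m in self._maf_iter():
            if not 0 < m <= 0.5:
                raise ValueError("every MAF must lie in (0, 0.5]")

    def _maf_iter(self):
        if isinstance(self.maf_spec, tuple) and len(self.maf_spec) == 3 \
                and self.maf_spec[0] == "uniform":
            lo, hi = float(self.maf_spec[1]), float(self.maf_spec[2])
            if not 0 < lo < hi <= 0.5:
                raise ValueError("uniform maf_spec needs 0 < low < high <= 0.5")
            return iter(())
        return iter(self.maf_spec)  # type: ignore[arg-type]

    def draw_mafs(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.maf_spec, tuple) and len(self.maf_spec) == 3 \
                and self.maf_spec[0] == "uniform":
            lo, hi = float(self.maf_spec[1]), float(self.maf_spec[2])
            return rng.uniform(lo, hi, size=self.n_variants)
        mafs = np.asarray(list(self.maf_spec), dtype=float)
        if mafs.size != self.n_variants:
            raise ValueError(
                f"maf_spec lists {mafs.size} MAFs but n_variants={self.n_variants}"
            )
        return mafs

    def with_overrides(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class StudyBundle:
    """Full output of one simulated study.

    Arrays are laid out variants x individuals.  ``phenotypes`` holds
    the analysis phenotype (binary 0/1 after median split when
    ``config.phenotype_kind == 'binary'``); one phenotype vector is
    drawn per variant.
    """

    config: SimConfig
    genotypes: np.ndarray      # (V, N) int8, true genotypes
    phenotypes: np.ndarray     # (V, N) float (quantitative) or int8 (binary)
    ref_counts: np.ndarray     # (V, N) int
    alt_counts: np.ndarray     # (V, N) int
    mafs: np.ndarray           # (V,) simulated allele frequencies
    coverage_rates: np.ndarray  # (V,) per-variant coverage rate
    pos: np.ndarray            # (V,) 1-based positions
    ref_alleles: np.ndarray    # (V,) str
    alt_alleles: np.ndarray    # (V,) str

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [f"var{i + 1}" for i in range(self.n_variants)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"sample{i + 1}" for i in range(self.n_individuals)]

    def coverage(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts


def simulate_study(config: SimConfig) -> StudyBundle:
    """Simulate a complete association study from a :class:`SimConfig`.

    Reproducible: the master seed spawns one independent substream per
    variant, so the bundle is identical on re-run and unchanged variants
    keep their data when ``n_variants`` grows.
    """
    master = np.random.default_rng(np.random.SeedSequence(config.seed))
    mafs = config.draw_mafs(master)
    rates = np.array(
        [config.count_model.coverage_law.draw_rate(master) for _ in range(config.n_variants)]
    )

    v, n = config.n_variants, config.n_individuals
    genotypes = np.empty((v, n), dtype=np.int8)
    ref_counts = np.empty((v, n), dtype=np.int32)
    alt_counts = np.empty((v, n), dtype=np.int32)
    pheno_dtype = np.int8 if config.phenotype_kind == "binary" else float
    phenotypes = np.empty((v, n), dtype=pheno_dtype)

    children = np.random.SeedSequence(config.seed).spawn(v)
    pairs = _ALLELE_PAIRS
    ref_alleles = np.array([pairs[i % len(pairs)][0] for i in range(v)])
    alt_alleles = np.array([pairs[i % len(pairs)][1] for i in range(v)])

    for i in range(v):
        rng = np.random.default_rng(children[i])
        g = simulate_genotypes(mafs[i], n, rng)
        y = assign_phenotypes(g, config.sigma, config.scenario, rng)
        if config.phenotype_kind == "binary":
            phenotypes[i] = median_split(y)
        else:
            phenotypes[i] = y
        ref_counts[i], alt_counts[i] = simulate_counts(
            g, config.count_model, rng,
            rate=rates[i], alleles=(ref_alleles[i], alt_alleles[i]),
        )
        genotypes[i] = g

    return StudyBundle(
        config=config,
        genotypes=genotypes,
        phenotypes=phenotypes,
        ref_counts=ref_counts,
        alt_counts=alt_counts,
        mafs=mafs,
        coverage_rates=rates,
        pos=np.arange(1, v + 1) * 100,
        ref_alleles=ref_alleles,
        alt_alleles=alt_alleles,
    )
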