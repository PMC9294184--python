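"""Generative-model checks: HWE genotypes, phenotypes, read counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adassoc.simulate import (
    CountModel,
    CoverageLaw,
    SimConfig,
    assign_phenotypes,
    hwe_genotype_probs,
    median_split,
    simulate_counts,
    simulate_genotypes,
    simulate_study,
)


@pytest.mark.parametrize(
    "maf,expected",
    [
        (0.5, (0.25, 0.5, 0.25)),
        (0.2, (0.64, 0.32, 0.04)),
        (1e-9, (1.0, 0.0, 0.0)),  # boundary limit
    ],
)
def test_hwe_probs(maf, expected):
    probs = hwe_genotype_probs(maf)
    assert probs == pytest.approx(expected, abs=1e-8)
    assert sum(probs) == pytest.approx(1.0)


@pytest.mark.parametrize("maf", [0.0, -0.1, 0.6, 1.0])
def test_hwe_probs_rejects_out_of_range(maf):
    with pytest.raises(ValueError):
        hwe_genotype_probs(maf)


def test_genotype_frequencies_match_hwe(rng):
    n = 100_000
    for maf in (0.5, 0.1):
        g = simulate_genotypes(maf, n, rng)
        probs = hwe_genotype_probs(maf)
        for code in (0, 1, 2):
            se = np.sqrt(probs[code] * (1 - probs[code]) / n)
            assert abs(np.mean(g == code) - probs[code]) < 4 * se


def test_genotypes_tiny_maf_all_reference(rng):
    assert not simulate_genotypes(1e-9, 1000, rng).any()


def test_genotypes_seed_determinism():
    a = simulate_genotypes(0.3, 500, np.random.default_rng(7))
    b = simulate_genotypes(0.3, 500, np.random.default_rng(7))
    np.testing.assert_array_equal(a, b)


def test_alternative_phenotype_mean_tracks_genotype(rng):
    n = 50_000
    g = np.full(n, 2, dtype=np.int8)
    y = assign_phenotypes(g, 6.5, "alternative", rng)
    assert abs(y.mean() - 2.0) < 3 * 6.5 / np.sqrt(n)


def test_null_phenotype_independent_of_genotype(rng):
    n = 100_000
    g = simulate_genotypes(0.3, n, rng)
    y = assign_phenotypes(g, 6.5, "null", rng)
    assert abs(np.corrcoef(g, y)[0, 1]) < 4 / np.sqrt(n)


def test_degenerate_sigma_limit(rng):
    g = simulate_genotypes(0.4, 100, rng)
    y = assign_phenotypes(g, 1e-12, "alternative", rng)
    np.testing.assert_allclose(y, g, atol=1e-9)


def test_phenotype_rejects_bad_sigma(rng):
    with pytest.raises(ValueError):
        assign_phenotypes(np.zeros(10, dtype=int), -1.0, "null", rng)


def test_median_split_examples():
    np.testing.assert_array_equal(median_split([1, 2, 3, 4]), [0, 0, 1, 1])
    np.testing.assert_array_equal(median_split([5, 5, 5, 5]), [0, 0, 0, 0])


@settings(derandomize=True, max_examples=50)
@given(st.integers(min_value=1, max_value=200), st.integers(min_value=0, max_value=2**31 - 1))
def test_median_split_halves_continuous_even_samples(half_n, seed):
    y = np.random.default_rng(seed).normal(size=2 * half_n)
    assert median_split(y).sum() == half_n


def test_counts_binomial_mean(rng, fixed_coverage_model):
    model = CountModel(
        coverage_law=CoverageLaw(kind="fixed", mean=10),
        error_rate=0.01,
        overdispersion=None,
    )
    g = np.ones(50_000, dtype=np.int8)
    ref, alt = simulate_counts(g, model, rng)
    np.testing.assert_array_equal(ref + alt, 10)
    assert abs(alt.mean() - 5.0) < 4 * np.sqrt(10 * 0.25 / g.size) * 10


def test_counts_negligible_error_rate_gives_no_alt_reads(rng):
    model = CountModel(
        coverage_law=CoverageLaw(kind="fixed", mean=30),
        error_rate=1e-12,
        overdispersion=None,
    )
    ref, alt = simulate_counts(np.zeros(2000, dtype=np.int8), model, rng)
    assert not alt.any()
    np.testing.assert_array_equal(ref, 30)


def test_counts_zero_coverage_degenerate(rng):
    model = CountModel(coverage_law=CoverageLaw(kind="fixed", mean=0))
    ref, alt = simulate_counts(np.array([0, 1, 2]), model, rng)
    assert not ref.any() and not alt.any()


def test_counts_conserve_coverage_with_overdispersion(rng):
    model = CountModel()  # default: gamma-Poisson coverage, beta-binomial
    g = rng.integers(0, 3, size=5000).astype(np.int8)
    ref, alt = simulate_counts(g, model, rng)
    assert (ref >= 0).all() and (alt >= 0).all()


def test_category_table_overrides_parametric(rng):
    table = {("A", "C", 1): (np.array([7, 7]), np.array([3, 3]))}
    model = CountModel(category_table=table)
    g = np.ones(100, dtype=np.int8)
    ref, alt = simulate_counts(g, model, rng, alleles=("A", "C"))
    np.testing.assert_array_equal(ref, 7)
    np.testing.assert_array_equal(alt, 3)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"error_rate": 0.0},
        {"error_rate": 0.6},
        {"overdispersion": -1.0},
        {"het_alt_fraction": 0.001},  # breaks mu0 < mu1 with default eps
    ],
)
def test_count_model_validation(kwargs):
    with pytest.raises(ValueError):
        CountModel(**kwargs)


def test_negative_binomial_coverage_requires_overdispersed_sd():
    with pytest.raises(ValueError):
        CoverageLaw(kind="negative_binomial", mean=22, sd=2.2)
    law = CoverageLaw(kind="negative_binomial", mean=22, sd=6.0)
    draws = law.draw(20_000, np.random.default_rng(3))
    assert (draws >= 0).all()
    assert abs(draws.mean() - 22) < 0.3


def test_study_seed_determinism():
    cfg = SimConfig(n_individuals=50, n_variants=5, seed=42)
    a, b = simulate_study(cfg), simulate_study(cfg)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    np.testing.assert_array_equal(a.phenotypes, b.phenotypes)
    np.testing.assert_array_equal(a.ref_counts, b.ref_counts)
    np.testing.assert_array_equal(a.alt_counts, b.alt_counts)
    np.testing.assert_array_equal(a.mafs, b.mafs)


def test_study_median_coverage_matches_design():
    cfg = SimConfig(n_individuals=400, n_variants=150, seed=5)
    bundle = simulate_study(cfg)
    median_cov = np.median(bundle.coverage())
    assert abs(median_cov - 22) <= 1.0


def test_study_binary_phenotypes_are_balanced(small_bundle):
    counts = small_bundle.phenotypes.sum(axis=1)
    assert (counts == small_bundle.n_individuals // 2).all()


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_individuals=1)
    with pytest.raises(ValueError):
        SimConfig(maf_spec=("uniform", 0.0, 0.5))
    with pytest.raises(ValueError):
        SimConfig(n_variants=2, maf_spec=[0.1, 0.7])
    with pytest.raises(ValueError):
        SimConfig(scenario="both")


def test_explicit_maf_list_is_used():
    cfg = SimConfig(n_individuals=10, n_variants=3, maf_spec=[0.1, 0.2, 0.5], seed=1)
    bundle = simulate_study(cfg)
    np.testing.assert_allclose(bundle.mafs, [0.1, 0.2, 0.5])
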