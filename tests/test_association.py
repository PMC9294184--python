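"""Association tests: proportional-odds and ratio regressions, and the scan."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from adassoc.association import (
    SampleAlignmentError,
    ordinal_logistic_test,
    ratio_linear_test,
    run_scan,
)
from adassoc.simulate import SimConfig, simulate_study
from adassoc.vcfio import bundle_to_table


def test_ordinal_exact_symmetry_gives_null_result():
    g = np.array([0, 1, 2, 0, 1, 2])
    y = np.array([0, 0, 0, 1, 1, 1])
    res = ordinal_logistic_test(g, y)
    assert res.estimate == pytest.approx(0.0, abs=1e-6)
    assert res.p_value == pytest.approx(1.0, abs=1e-6)


def test_ordinal_two_levels_equals_binary_logistic():
    """With two genotype levels the fit is binary logistic regression."""
    rng = np.random.default_rng(8)
    for _ in range(5):
        g = rng.choice([0, 1], size=300, p=[0.8, 0.2])
        y = rng.normal(0.5 * g, 2.0)
        res = ordinal_logistic_test(g, y)
        oracle = sm.Logit(g, sm.add_constant(y)).fit(disp=0)
        assert res.estimate == pytest.approx(oracle.params[1], abs=1e-6)
        assert res.p_value == pytest.approx(oracle.pvalues[1], abs=1e-6)


def test_ordinal_three_levels_matches_statsmodels():
    rng = np.random.default_rng(21)
    g = rng.choice([0, 1, 2], size=800, p=[0.5, 0.4, 0.1])
    y = rng.normal(0.4 * g, 2.0)
    res = ordinal_logistic_test(g, y)
    oracle = OrderedModel(g, y[:, None], distr="logit").fit(
        method="bfgs", disp=0, gtol=1e-9)
    assert res.estimate == pytest.approx(oracle.params[0], abs=1e-5)
    assert res.std_error == pytest.approx(oracle.bse[0], abs=1e-5)


def test_ordinal_monomorphic_is_missing():
    res = ordinal_logistic_test(np.zeros(50), np.arange(50.0))
    assert res.is_missing


def test_ordinal_drops_missing_genotypes():
    g = np.array([0, 1, 2, -1, -1, 0, 1, 2])
    y = np.arange(8.0)
    res = ordinal_logistic_test(g, y)
    assert res.n_used == 6


def test_ordinal_length_mismatch():
    with pytest.raises(ValueError):
        ordinal_logistic_test(np.zeros(5), np.zeros(4))


def test_ratio_matches_pearson_correlation_test():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n = rng.integers(10, 80)
        r = rng.random(n)
        y = rng.normal(size=n)
        res = ratio_linear_test(r, y)
        oracle = stats.pearsonr(y, r)
        assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-10)


def test_ratio_perfect_fit_reports_tiny_pvalue():
    res = ratio_linear_test(np.array([0, 0, 1, 1.0]), np.array([0, 0, 1, 1.0]))
    assert res.estimate == pytest.approx(1.0)
    assert 0 < res.p_value < 1e-10


def test_ratio_constant_phenotype_missing():
    res = ratio_linear_test(np.array([0.1, 0.5, 0.9]), np.ones(3))
    assert res.is_missing


def test_ratio_excludes_nan_pairs():
    r = np.array([0.1, np.nan, 0.5, 0.9, np.nan])
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = ratio_linear_test(r, y)
    assert res.n_used == 3


def test_location_invariance_of_both_tests():
    """Shifting the phenotype leaves slope-test p-values unchanged."""
    rng = np.random.default_rng(11)
    g = rng.choice([0, 1, 2], size=400, p=[0.5, 0.4, 0.1])
    y = rng.normal(0.3 * g, 2.0)
    ratios = rng.random(400)
    for shift in (17.5, -3.25):
        a = ordinal_logistic_test(g, y)
        b = ordinal_logistic_test(g, y + shift)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-8)
        c = ratio_linear_test(ratios, y)
        d = ratio_linear_test(ratios, y + shift)
        assert d.p_value == pytest.approx(c.p_value, abs=1e-8)


def test_scan_cardinality(small_bundle):
    res = run_scan(small_bundle)
    assert len(res) == small_bundle.n_variants * 3
    assert set(res["method"]) == {"oracle_ordinal", "called_ordinal", "ratio_linear"}
    assert list(res.columns) == [
        "variant_id", "chrom", "pos", "method", "estimate", "se", "pvalue", "n_used",
    ]


def test_scan_null_pvalues_uniform():
    """Under the null every arm's p-values are Uniform(0,1)."""
    cfg = SimConfig(n_individuals=250, n_variants=1200, scenario="null",
                    phenotype_kind="binary", seed=314,
                    maf_spec=("uniform", 0.05, 0.5))
    res = run_scan(simulate_study(cfg))
    for method, grp in res.groupby("method"):
        p = grp["pvalue"].dropna().to_numpy()
        assert len(p) > 1000
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.001, method


def test_scan_vcf_table_path(small_bundle):
    table = bundle_to_table(small_bundle)
    pheno = pd.DataFrame({
        "sample_id": small_bundle.sample_ids,
        "phenotype": small_bundle.phenotypes[0],
    })
    res = run_scan(table, pheno, methods=("called_ordinal", "ratio_linear"))
    assert len(res) == small_bundle.n_variants * 2
    with pytest.raises(ValueError):
        run_scan(table, pheno, methods=("oracle_ordinal",))


def test_scan_alignment_error_lists_offenders(small_bundle):
    table = bundle_to_table(small_bundle)
    pheno = pd.DataFrame({
        "sample_id": [s + "_x" for s in small_bundle.sample_ids],
        "phenotype": small_bundle.phenotypes[0],
    })
    with pytest.raises(SampleAlignmentError) as err:
        run_scan(table, pheno, methods=("ratio_linear",))
    assert "sample1_x" in str(err.value)


def test_scan_monomorphic_variant_handling():
    """A monomorphic variant yields a missing ordinal p-value while the
    ratio arm can still be informative."""
    cfg = SimConfig(n_individuals=60, n_variants=2, seed=77,
                    maf_spec=[1e-9, 0.4], scenario="null")
    bundle = simulate_study(cfg)
    res = run_scan(bundle)
    mono = res[(res.variant_id == "var1") & (res.method == "oracle_ordinal")]
    assert mono["pvalue"].isna().all()
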