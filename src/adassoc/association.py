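"""Per-variant association tests.

Three tests are supported, all with the genotype-side quantity as the
response and the phenotype as the sole explanatory variable:

- ``oracle_ordinal``: proportional-odds (cumulative logit) regression of
  the *true* simulated genotype on the phenotype — the unattainable
  upper bound used to benchmark the other two,
- ``called_ordinal``: the same model on genotypes called from read
  counts — the classical analysis,
- ``ratio_linear``: ordinary least squares of the alternative-read
  ratio alt/(ref+alt) on the phenotype — the count-based alternative
  that avoids genotype calling.

Both ordinal tests use a Wald test on the phenotype coefficient; the
linear test uses the two-sided t-test on the slope (identical to the
Pearson-correlation t-test).  Samples with a missing response (missing
call, zero coverage) are dropped per variant.  Degenerate fits —
monomorphic response, non-convergence, separation — yield a missing
p-value rather than a spurious one; downstream rejection rates use the
non-missing count as denominator.

The proportional-odds likelihood is maximised by a damped Newton
iteration with an analytic gradient; with two observed response levels
the model is exactly binary logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .calling import DEFAULT_CALLER_ERROR_RATE, alt_ratio, call_genotypes
from .simulate import MISSING, StudyBundle

__all__ = [
    "AssocResult",
    "SampleAlignmentError",
    "ordinal_logistic_test",
    "ratio_linear_test",
    "run_scan",
]

ALL_METHODS = ("oracle_ordinal", "called_ordinal", "ratio_linear")
_MAX_ABS_COEF = 50.0  # |beta| beyond this is treated as separation


class SampleAlignmentError(ValueError):
    """Raised when genotype/count samples and phenotype samples differ."""

    def __init__(self, missing_pheno, missing_data):
        self.missing_pheno = sorted(missing_pheno)
        self.missing_data = sorted(missing_data)
        super().__init__(
            "sample mismatch between data and phenotype table; "
            f"no phenotype for {self.missing_pheno or 'none'}, "
            f"no data for {self.missing_data or 'none'}"
        )


@dataclass(frozen=True)
class AssocResult:
    """Result of one association test at one variant.

    ``p_value`` is NaN exactly when the fit was degenerate or failed
    (fewer than two response levels, non-convergence, separation,
    zero-variance covariate).
    """

    variant_id: str
    method: str
    estimate: float
    std_error: float
    p_value: float
    n_used: int

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.p_value)


def _failed(variant_id: str, method: str, n_used: int) -> AssocResult:
    return AssocResult(variant_id, method, np.nan, np.nan, np.nan, n_used)


# ---------------------------------------------------------------------------
# proportional-odds fit


def _polr_negloglik_grad(theta: np.ndarray, y: np.ndarray, x: np.ndarray, k: int,
                         w: np.ndarray | None = None):
    """Negative log-likelihood and gradient of the cumulative-logit model.

    Parameters are ``theta = (cut_1 .. cut_{k-1}, beta)``; the linear
    predictor for P(Y <= j | x) is sigmoid(cut_j - beta * x).  ``w`` are
    optional case weights (used to collapse duplicated (y, x) rows).
    """
    if w is None:
        w = np.ones(x.size)
    cuts = theta[:-1]
    beta = theta[-1]
    eta = cuts[None, :] - beta * x[:, None]          # (m, k-1)
    cum = expit(eta)
    upper = np.concatenate([cum, np.ones((x.size, 1))], axis=1)
    lower = np.concatenate([np.zeros((x.size, 1)), cum], axis=1)
    idx = np.arange(x.size)
    p = upper[idx, y] - lower[idx, y]
    p = np.maximum(p, 1e-300)
    nll = -np.sum(w * np.log(p))

    dcum = cum * (1.0 - cum)                          # sigma'(eta)
    # d log p_i / d eta_j: +sigma'(eta_{y_i})/p at j = y_i (if y_i < k-1),
    #                      -sigma'(eta_{y_i - 1})/p at j = y_i - 1 (if y_i > 0)
    a = np.zeros(x.size)
    hi = y < k - 1
    a[hi] = dcum[idx[hi], y[hi]] / p[hi]
    b = np.zeros(x.size)
    lo = y > 0
    b[lo] = dcum[idx[lo], y[lo] - 1] / p[lo]

    grad = np.empty(k)
    for j in range(k - 1):
        grad[j] = -(np.sum(w[y == j] * a[y == j]) - np.sum(w[y == j + 1] * b[y == j + 1]))
    grad[-1] = np.sum(w * x * (a - b))                # d eta/d beta = -x
    return nll, grad


def _fit_proportional_odds(y: np.ndarray, x: np.ndarray):
    """Maximum-likelihood proportional-odds fit; returns (beta, se) or None.

    ``y`` must already be coded 0..k-1 with every level present.  Damped
    Newton with the Hessian taken as a central finite difference of the
    analytic gradient; ``None`` signals non-convergence or separation.
    """
    k = int(y.max()) + 1
    n = y.size
    # collapse duplicated (y, x) rows: with a binary or categorical
    # covariate the likelihood reduces to a handful of weighted cells
    ux = np.unique(x)
    if ux.size * k <= 64:
        code = y * ux.size + np.searchsorted(ux, x)
        w_full = np.bincount(code, minlength=k * ux.size).astype(float)
        nz = w_full > 0
        cells = np.arange(k * ux.size)
        yw = (cells // ux.size)[nz]
        xw = ux[cells % ux.size][nz]
        w = w_full[nz]
    else:
        yw, xw, w = y, x, None
    # start: empirical cumulative logits, zero slope
    counts = np.bincount(y, minlength=k)
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 1.0 / (n + 1), 1.0 - 1.0 / (n + 1))
    theta = np.concatenate([np.log(cum / (1.0 - cum)), [0.0]])

    nll, grad = _polr_negloglik_grad(theta, yw, xw, k, w)
    for _ in range(100):
        hess = _fd_hessian(theta, yw, xw, k, w)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        # backtracking line search on the NLL
        t = 1.0
        for _ in range(30):
            cand = theta - t * step
            nll_new, grad_new = _polr_negloglik_grad(cand, yw, xw, k, w)
            if nll_new <= nll:
                break
            t *= 0.5
        else:
            return None
        theta, nll, grad = cand, nll_new, grad_new
        if np.max(np.abs(grad)) < 1e-6:
            break
    else:
        return None

    if abs(theta[-1]) > _MAX_ABS_COEF:
        return None
    hess = _fd_hessian(theta, yw, xw, k, w)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    var = cov[-1, -1]
    if not np.isfinite(var) or var <= 0:
        return None
    return float(theta[-1]), float(np.sqrt(var))


def _fd_hessian(theta: np.ndarray, y: np.ndarray, x: np.ndarray, k: int,
                w: np.ndarray | None = None) -> np.ndarray:
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    hess = np.empty((k, k))
    for j in range(k):
        tp = theta.copy()
        tp[j] += h[j]
        tm = theta.copy()
        tm[j] -= h[j]
        _, gp = _polr_negloglik_grad(tp, y, x, k, w)
        _, gm = _polr_negloglik_grad(tm, y, x, k, w)
        hess[:, j] = (gp - gm) / (2.0 * h[j])
    return 0.5 * (hess + hess.T)


def ordinal_logistic_test(
    genotype: np.ndarray,
    phenotype: np.ndarray,
    *,
    variant_id: str = "",
    method: str = "called_ordinal",
) -> AssocResult:
    """Proportional-odds regression of genotype (ordinal response, codes
    0/1/2) on phenotype; Wald test on the phenotype coefficient.

    Missing genotypes (code -1 or NaN) are excluded pairwise.  With only
    two genotype levels observed the model reduces to binary logistic
    regression; with fewer than two levels, on non-convergence, or on
    separation the p-value is missing.
    """
    g = np.asarray(genotype, dtype=float)
    x = np.asarray(phenotype, dtype=float)
    if g.shape != x.shape:
        raise ValueError("genotype and phenotype lengths differ")
    keep = np.isfinite(g) & (g != MISSING) & np.isfinite(x)
    g, x = g[keep], x[keep]
    n_used = g.size
    if n_used < 3 or np.ptp(x) == 0:
        return _failed(variant_id, method, n_used)

    levels = np.unique(g)
    if levels.size < 2:
        return _failed(variant_id, method, n_used)
    y = np.searchsorted(levels, g).astype(np.int64)

    fit = _fit_proportional_odds(y, x)
    if fit is None:
        return _failed(variant_id, method, n_used)
    beta, se = fit
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return AssocResult(variant_id, method, beta, se, p, n_used)


def ratio_linear_test(
    ratio: np.ndarray,
    phenotype: np.ndarray,
    *,
    variant_id: str = "",
    method: str = "ratio_linear",
) -> AssocResult:
    """OLS of the alternative-read ratio on the phenotype; two-sided
    t-test on the slope.

    Missing ratios (zero-coverage samples) are excluded pairwise.  A
    zero-variance response or covariate, or fewer than 3 complete
    pairs, yields a missing p-value.  A perfect fit (zero residuals)
    reports the smallest positive float rather than p = 0.
    """
    r = np.asarray(ratio, dtype=float)
    x = np.asarray(phenotype, dtype=float)
    if r.shape != x.shape:
        raise ValueError("ratio and phenotype lengths differ")
    keep = np.isfinite(r) & np.isfinite(x)
    r, x = r[keep], x[keep]
    n_used = r.size
    if n_used < 3 or np.ptp(x) == 0 or np.ptp(r) == 0:
        return _failed(variant_id, method, n_used)
    res = stats.linregress(x, r)
    p = float(res.pvalue)
    if not np.isfinite(p):
        return _failed(variant_id, method, n_used)
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return AssocResult(variant_id, method, float(res.slope), float(res.stderr), p, n_used)


# ---------------------------------------------------------------------------
# study-level scan


def run_scan(
    data,
    phenotype=None,
    methods=ALL_METHODS,
    *,
    error_rate: float | None = None,
) -> pd.DataFrame:
    """Run the requested association tests at every variant.

    ``data`` is either a simulated :class:`StudyBundle` (phenotypes are
    taken from the bundle, one vector per variant) or a VCF-derived
    ``VariantTable``, in which case ``phenotype`` must be a DataFrame
    with columns ``sample_id`` and ``phenotype`` covering exactly the
    table's samples; the oracle arm is only defined for simulated data.

    Returns a tidy DataFrame with one row per variant per method:
    variant_id, chrom, pos, method, estimate, se, pvalue, n_used.
    """
    if isinstance(data, StudyBundle):
        return _scan_bundle(data, methods, error_rate)
    return _scan_table(data, phenotype, methods, error_rate)


def _scan_bundle(bundle: StudyBundle, methods, error_rate) -> pd.DataFrame:
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")
    # the caller assumes its own (base-quality) error model; it does not
    # know the effective noise of the generative count model
    eps = DEFAULT_CALLER_ERROR_RATE if error_rate is None else error_rate
    need_calls = "called_ordinal" in methods
    need_ratio = "ratio_linear" in methods

    rows = []
    ids = bundle.variant_ids
    for i in range(bundle.n_variants):
        y = bundle.phenotypes[i].astype(float)
        vid = ids[i]
        if "oracle_ordinal" in methods:
            rows.append(ordinal_logistic_test(
                bundle.genotypes[i], y, variant_id=vid, method="oracle_ordinal"))
        if need_calls:
            called, _ = call_genotypes(bundle.ref_counts[i], bundle.alt_counts[i], eps)
            rows.append(ordinal_logistic_test(
                called, y, variant_id=vid, method="called_ordinal"))
        if need_ratio:
            ratios = alt_ratio(bundle.ref_counts[i], bundle.alt_counts[i])
            rows.append(ratio_linear_test(
                ratios, y, variant_id=vid, method="ratio_linear"))
    df = _results_frame(rows)
    pos = dict(zip(ids, bundle.pos))
    df["chrom"] = bundle.config.chrom
    df["pos"] = df["variant_id"].map(pos)
    return df[["variant_id", "chrom", "pos", "method", "estimate", "se", "pvalue", "n_used"]]


def _scan_table(table, phenotype, methods, error_rate) -> pd.DataFrame:
    if phenotype is None:
        raise ValueError("a phenotype table is required for VCF-derived data")
    if "oracle_ordinal" in methods:
        raise ValueError("the oracle arm requires simulated data with true genotypes")
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")

    pheno = phenotype.set_index("sample_id")["phenotype"]
    table_samples = set(table.samples)
    pheno_samples = set(pheno.index)
    if table_samples != pheno_samples:
        raise SampleAlignmentError(
            missing_pheno=table_samples - pheno_samples,
            missing_data=pheno_samples - table_samples,
        )
    y = pheno.reindex(table.samples).to_numpy(dtype=float)

    rows = []
    for i, vid in enumerate(table.variant_ids):
        if "called_ordinal" in methods:
            g = table.gt[i].astype(float)
            g[table.gt[i] == MISSING] = np.nan
            rows.append(ordinal_logistic_test(g, y, variant_id=vid, method="called_ordinal"))
        if "ratio_linear" in methods:
            ref = table.ad_ref[i].astype(float)
            alt = table.ad_alt[i].astype(float)
            bad = (table.ad_ref[i] == MISSING) | (table.ad_alt[i] == MISSING)
            ratios = np.where(bad, np.nan, alt_ratio(np.maximum(ref, 0), np.maximum(alt, 0)))
            rows.append(ratio_linear_test(ratios, y, variant_id=vid, method="ratio_linear"))
    df = _results_frame(rows)
    meta = table.variants.set_index("variant_id")
    df["chrom"] = df["variant_id"].map(meta["chrom"])
    df["pos"] = df["variant_id"].map(meta["pos"])
    return df[["variant_id", "chrom", "pos", "method", "estimate", "se", "pvalue", "n_used"]]


def _results_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in rows],
            "method": [r.method for r in rows],
            "estimate": [r.estimate for r in rows],
            "se": [r.std_error for r in rows],
            "pvalue": [r.p_value for r in rows],
            "n_used": [r.n_used for r in rows],
        }
    )
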