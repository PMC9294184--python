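"""Rejection-rate summaries: type-I error and power, overall and stratified.

The type-I error rate (null scenario) and statistical power
(alternative scenario) of each test are estimated as the proportion of
non-missing p-values at or below alpha across simulated variants.
Summaries can be stratified by minor allele frequency, per-variant
coverage, or per-variant genotype quality, with quartile bounds of the
realized per-variant statistic by default or user-supplied cut points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import MISSING

__all__ = [
    "RejectionRate",
    "rejection_rate",
    "compute_maf",
    "quartile_bounds",
    "stratify_variants",
    "summarize_study",
    "DEFAULT_MAF_BOUNDS",
]

# first bin "MAF <= 0.05" is the rare-variant stratum of interest
DEFAULT_MAF_BOUNDS = (0.05, 0.1, 0.25)


@dataclass(frozen=True)
class RejectionRate:
    """Proportion of non-missing p-values at or below alpha.

    ``defined`` is False when every p-value is missing, in which case
    ``proportion`` is NaN.
    """

    n_total: int
    n_missing: int
    n_rejected: int
    proportion: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.proportion)

    @property
    def mc_se(self) -> float:
        """Binomial Monte-Carlo standard error of the proportion."""
        n = self.n_total - self.n_missing
        if n == 0 or not self.defined:
            return np.nan
        return float(np.sqrt(self.proportion * (1.0 - self.proportion) / n))


def rejection_rate(pvalues, alpha: float = 0.05) -> RejectionRate:
    """Fraction of non-missing p-values <= alpha (missing = NaN)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    n_total = p.size
    ok = np.isfinite(p)
    n_nonmissing = int(ok.sum())
    n_rejected = int(np.sum(p[ok] <= alpha))
    prop = n_rejected / n_nonmissing if n_nonmissing else np.nan
    return RejectionRate(n_total, n_total - n_nonmissing, n_rejected, prop)


def compute_maf(genotypes) -> float:
    """Minor allele frequency from 0/1/2 genotype codes.

    Alt-allele frequency q = (n1 + 2*n2) / (2 * n_nonmissing), folded to
    min(q, 1-q).  Missing codes (-1 or NaN) are excluded; all-missing
    input is undefined.
    """
    g = np.asarray(genotypes, dtype=float)
    ok = np.isfinite(g) & (g != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    q = g[ok].sum() / (2.0 * n)
    return float(min(q, 1.0 - q))


def quartile_bounds(values) -> tuple[float, float, float]:
    """Empirical quartiles (Q1, median, Q3) of a per-variant statistic."""
    v = np.asarray(values, dtype=float)
    q1, q2, q3 = np.percentile(v[np.isfinite(v)], [25, 50, 75])
    return float(q1), float(q2), float(q3)


def stratify_variants(values, bounds: Sequence[float]) -> np.ndarray:
    """Assign each variant to a stratum from interval cut points.

    ``bounds = (b1, .., bk)`` defines k+1 strata: (-inf, b1], (b1, b2],
    ..., (bk, inf) — left-open, right-closed, except the lowest which
    includes everything at or below b1.  Returns 1-based stratum codes.
    """
    b = np.asarray(bounds, dtype=float)
    if b.size == 0:
        raise ValueError("at least one bound is required")
    if np.any(np.diff(b) <= 0):
        raise ValueError("bounds must be strictly increasing")
    v = np.asarray(values, dtype=float)
    # side="left": a value equal to a bound falls in the lower stratum
    return (np.searchsorted(b, v, side="left") + 1).astype(int)


def _stratum_label(bounds: Sequence[float], code: int) -> str:
    b = list(bounds)
    if code == 1:
        return f"<={b[0]:g}"
    if code == len(b) + 1:
        return f">{b[-1]:g}"
    return f"({b[code - 2]:g},{b[code - 1]:g}]"


def summarize_study(
    results: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    stratifiers: Sequence[str] = ("none", "maf", "coverage", "gq"),
    bounds: dict | None = None,
) -> pd.DataFrame:
    """Rejection-rate table per method, overall and per stratum.

    Parameters
    ----------
    results
        Tidy scan output: one row per variant per method with columns
        ``variant_id``, ``method``, ``pvalue``.
    meta
        Per-variant metadata with ``variant_id`` and, for each requested
        stratifier, a column ``maf`` / ``mean_coverage`` / ``mean_gq``.
    alpha
        Rejection threshold.
    stratifiers
        Any of ``none`` (overall), ``maf``, ``coverage``, ``gq``.
    bounds
        Optional ``{stratifier: cut points}``; defaults are the rare-
        variant MAF bins (0.05, 0.1, 0.25) and realized quartiles of the
        per-variant statistic for coverage and genotype quality.

    Returns one row per method x stratifier x stratum with the stratum
    bounds, variant counts, missing-p count, the rejection proportion
    among non-missing p-values and its Monte-Carlo standard error.
    """
    stat_col = {"maf": "maf", "coverage": "mean_coverage", "gq": "mean_gq"}
    bounds = dict(bounds or {})
    merged = results.merge(meta, on="variant_id", how="left", validate="many_to_one")

    rows = []
    for strat in stratifiers:
        if strat == "none":
            groups = [("all", None, merged)]
        else:
            col = stat_col.get(strat)
            if col is None:
                raise ValueError(f"unknown stratifier {strat!r}")
            if col not in merged.columns:
                raise ValueError(f"metadata lacks column {col!r} for stratifier {strat!r}")
            if strat in bounds:
                b = tuple(bounds[strat])
            elif strat == "maf":
                b = DEFAULT_MAF_BOUNDS
            else:
                q1, _, q3 = quartile_bounds(meta[col])
                med = float(np.percentile(meta[col][np.isfinite(meta[col])], 50))
                b = _dedupe_bounds((q1, med, q3))
            codes = stratify_variants(merged[col].to_numpy(), b)
            groups = [
                (_stratum_label(b, c), c, merged[codes == c])
                for c in range(1, len(b) + 2)
            ]
        for label, _, sub in groups:
            for method, mgrp in sub.groupby("method", sort=False):
                rr = rejection_rate(mgrp["pvalue"].to_numpy(), alpha)
                rows.append({
                    "method": method,
                    "stratifier": strat,
                    "stratum": label,
                    "n_variants": rr.n_total,
                    "n_missing_p": rr.n_missing,
                    "rejection_rate": rr.proportion,
                    "mc_se": rr.mc_se,
                })
    return pd.DataFrame(rows)


def paired_power_gap(
    results: pd.DataFrame,
    method_a: str = "ratio_linear",
    method_b: str = "called_ordinal",
    alpha: float = 0.05,
    variant_ids=None,
) -> tuple[float, float]:
    """Rejection-rate difference method_a - method_b with its paired MC SE.

    Both methods are evaluated on the same simulated variants, so the
    Monte-Carlo standard error of the difference comes from the
    per-variant rejection-indicator differences (missing p-values count
    as non-rejections).  ``variant_ids`` optionally restricts to a
    stratum.
    """
    piv = results.pivot(index="variant_id", columns="method", values="pvalue")
    if variant_ids is not None:
        piv = piv.loc[piv.index.intersection(list(variant_ids))]
    d = (piv[method_a] <= alpha).astype(float) - (piv[method_b] <= alpha).astype(float)
    if len(d) < 2:
        raise ValueError("need at least 2 variants for a paired gap")
    return float(d.mean()), float(d.std(ddof=1) / np.sqrt(len(d)))


def _dedupe_bounds(b):
    """Collapse duplicate quartile cut points (degenerate statistics)."""
    out = []
    for v in b:
        if not out or v > out[-1]:
            out.append(v)
    if not out:
        raise ValueError("degenerate statistic: no usable bounds")
    return tuple(out)
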