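"""Genotype calling from allele counts with a flat prior.

Diploid binomial likelihood model: given a per-read miscall probability
epsilon, a read supports the alternative allele with probability
epsilon, 0.5, or 1 - epsilon for genotypes 0, 1, 2.  The call is the
maximum-posterior genotype under the prior (flat, 1/3 each, by
default), with the genotype quality GQ reported as the gap between the
best and second-best phred-scaled normalised posteriors, capped at 99.
Samples with zero coverage carry no information and are called missing
with GQ 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import MISSING

__all__ = [
    "CalledGenotype",
    "DEFAULT_CALLER_ERROR_RATE",
    "FLAT_PRIOR",
    "genotype_likelihoods",
    "call_genotype",
    "call_genotypes",
    "alt_ratio",
]

FLAT_PRIOR = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
GQ_CAP = 99
# standard per-read miscall probability assumed by the caller (phred 20)
DEFAULT_CALLER_ERROR_RATE = 0.01


@dataclass(frozen=True)
class CalledGenotype:
    """One genotype call: code in {0,1,2} or missing (-1), phred GQ, and
    the per-genotype log-likelihoods it was derived from."""

    genotype: int
    gq: int
    log_likelihoods: tuple[float, float, float]

    @property
    def is_missing(self) -> bool:
        return self.genotype == MISSING


def genotype_likelihoods(ref_count, alt_count, error_rate: float = 0.01) -> np.ndarray:
    """Log-likelihoods (natural log) of genotypes 0/1/2 given counts.

    log L(g) = alt * log(pi_g) + ref * log(1 - pi_g) with
    pi = (epsilon, 0.5, 1 - epsilon), up to a shared binomial constant.
    Zero-coverage input yields three equal (zero) log-likelihoods.
    Accepts scalars (returns shape (3,)) or arrays (returns (..., 3)).
    """
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be nonnegative")
    pi = np.array([error_rate, 0.5, 1.0 - error_rate])
    ll = alt[..., None] * np.log(pi) + ref[..., None] * np.log1p(-pi)
    return ll


def call_genotype(
    likelihoods,
    prior=FLAT_PRIOR,
    *,
    coverage: int | None = None,
) -> CalledGenotype:
    """Call a single genotype from log-likelihoods and a prior.

    The call is argmax of the posterior; exact posterior ties are broken
    toward the heterozygote, then the lower genotype code.  GQ is the
    GATK-style difference between the second-best and best normalised
    phred posteriors, rounded and capped at 99.  If ``coverage`` is
    given as 0 the sample is uninformative: missing genotype, GQ 0.
    """
    ll = np.asarray(likelihoods, dtype=float)
    if ll.shape != (3,) or not np.all(np.isfinite(ll)):
        raise ValueError("likelihoods must be three finite log-likelihoods")
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (3,) or np.any(prior < 0) or not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must be three nonnegative probabilities summing to 1")

    if coverage == 0:
        return CalledGenotype(MISSING, 0, tuple(ll))

    with np.errstate(divide="ignore"):
        log_post = ll + np.log(prior)
    best = np.max(log_post[np.isfinite(log_post)])
    tied = np.isclose(log_post, best, rtol=0, atol=1e-12)
    g = 1 if tied[1] else int(np.flatnonzero(tied)[0])

    # phred-scaled, normalised so the best genotype has PL 0
    pl = -10.0 * (log_post - best) / np.log(10.0)
    pl_sorted = np.sort(pl[np.isfinite(pl)])
    gap = pl_sorted[1] - pl_sorted[0] if pl_sorted.size > 1 else float("inf")
    gq = GQ_CAP if not np.isfinite(gap) else int(min(GQ_CAP, round(gap)))
    return CalledGenotype(g, gq, tuple(ll))


def call_genotypes(
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    error_rate: float = 0.01,
    prior=FLAT_PRIOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised flat-prior calling over arrays of (ref, alt) counts.

    Returns ``(genotypes, gq)`` with genotype -1 and GQ 0 where coverage
    is zero.  Equivalent to mapping :func:`call_genotype` over samples.
    """
    ref = np.asarray(ref_counts)
    alt = np.asarray(alt_counts)
    ll = genotype_likelihoods(ref, alt, error_rate)
    log_prior = np.log(np.asarray(prior, dtype=float))
    with np.errstate(divide="ignore"):
        log_post = ll + log_prior

    best = np.max(log_post, axis=-1, keepdims=True)
    tied = np.isclose(log_post, best, rtol=0, atol=1e-12)
    # tie-break: heterozygote first, then genotype 0, then 2
    order = np.array([1, 0, 2])
    g = order[np.argmax(tied[..., order], axis=-1)].astype(np.int8)

    pl = -10.0 * (log_post - best) / np.log(10.0)
    pl_sorted = np.sort(np.where(np.isfinite(pl), pl, np.inf), axis=-1)
    gap = pl_sorted[..., 1] - pl_sorted[..., 0]
    gq = np.minimum(GQ_CAP, np.round(np.where(np.isfinite(gap), gap, GQ_CAP))).astype(np.int16)

    zero_cov = (ref + alt) == 0
    g = np.where(zero_cov, np.int8(MISSING), g)
    gq = np.where(zero_cov, np.int16(0), gq)
    return g, gq


def alt_ratio(ref_count, alt_count):
    """Alternative-read ratio alt/(ref+alt); NaN where coverage is 0.

    This is the response variable of the count-based association test.
    Accepts scalars or arrays.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be nonnegative")
    cov = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cov > 0, alt / cov, np.nan)
    if out.ndim == 0:
        return float(out)
    return out
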