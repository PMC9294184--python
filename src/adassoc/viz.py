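"""Manhattan and linkage-disequilibrium visualisation.

LD is measured as r^2 between genotype dosage vectors (squared Pearson
correlation over pairwise-complete samples), the composite-genotype LD
statistic that needs no haplotype phasing.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .simulate import MISSING

__all__ = ["ld_r2", "ld_matrix", "manhattan", "ld_plot"]

_METHOD_COLORS = {
    "called_ordinal": "#1f77b4",
    "ratio_linear": "#2ca02c",
    "oracle_ordinal": "#7f7f7f",
}


def ld_r2(g1, g2) -> float:
    """Squared dosage correlation between two variants.

    Missing codes (-1 or NaN) are excluded pairwise; requires at least
    two complete pairs and both variants polymorphic on them, otherwise
    the statistic is undefined and a ValueError is raised.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    keep = np.isfinite(a) & np.isfinite(b) & (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("fewer than 2 complete pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD undefined for a monomorphic variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(genotypes: np.ndarray, variant_ids=None) -> pd.DataFrame:
    """Pairwise r^2 matrix for a variants x samples genotype array.

    Undefined pairs (monomorphic variants) are NaN; the diagonal is 1
    for polymorphic variants.
    """
    g = np.asarray(genotypes, dtype=float)
    v = g.shape[0]
    ids = list(variant_ids) if variant_ids is not None else [f"var{i+1}" for i in range(v)]
    out = np.full((v, v), np.nan)
    for i in range(v):
        for j in range(i, v):
            try:
                out[i, j] = out[j, i] = ld_r2(g[i], g[j])
            except ValueError:
                pass
    return pd.DataFrame(out, index=ids, columns=ids)


def manhattan(results: pd.DataFrame, path, title: str | None = None) -> None:
    """Manhattan plot: -log10(p) against position, one colour per method.

    ``results`` is a tidy scan frame with columns pos, method, pvalue;
    missing p-values are omitted.  Raises on empty input or when every
    p-value is missing.
    """
    if len(results) == 0:
        raise ValueError("no results to plot")
    ok = results.dropna(subset=["pvalue"])
    if len(ok) == 0:
        raise ValueError("all p-values are missing")
    fig, ax = plt.subplots(figsize=(9, 4))
    for method, grp in ok.groupby("method", sort=False):
        ax.scatter(
            grp["pos"], -np.log10(grp["pvalue"]),
            s=12, label=method, alpha=0.8,
            color=_METHOD_COLORS.get(method),
        )
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ld_plot(r2: pd.DataFrame, path, title: str | None = None) -> None:
    """Heatmap of a pairwise r^2 matrix."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(r2.to_numpy(), vmin=0, vmax=1, cmap="Reds", interpolation="nearest")
    fig.colorbar(im, ax=ax, label=r"$r^2$")
    ax.set_xlabel("variant index")
    ax.set_ylabel("variant index")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
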