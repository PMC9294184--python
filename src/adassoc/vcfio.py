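"""VCF input/output with GT, AD and GQ FORMAT fields.

Reading and writing go through pysam.  Reading parses biallelic
genotypes to 0/1/2 dosage codes (phased or unphased), allelic depths to
(ref, alt) pairs and genotype qualities; multiallelic sites are carried
through with a flag and excluded — never truncated — by the biallelic
filter.  Writing emits VCF 4.2 with a GT:AD:GQ FORMAT, deterministic
record order, and GQ capped at 99.

Coordinates are 1-based inclusive throughout, per the VCF standard;
optional region queries use 1-based closed intervals ``chrom:start-end``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .calling import GQ_CAP, call_genotypes
from .simulate import MISSING, StudyBundle

__all__ = [
    "VariantTable",
    "read_vcf",
    "write_vcf",
    "filter_complete_biallelic",
    "read_phenotypes",
    "write_phenotypes",
    "bundle_to_table",
]


@dataclass
class VariantTable:
    """Tabular view of a VCF: per-variant records and per-sample arrays.

    ``gt``, ``ad_ref``, ``ad_alt`` and ``gq`` are variants x samples
    integer arrays with -1 marking missing entries.  ``variants`` holds
    chrom, pos, variant_id, ref, alt and a ``multiallelic`` flag; for
    flagged sites the per-sample arrays are left missing rather than
    truncated to two alleles.
    """

    samples: list[str]
    variants: pd.DataFrame
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    gq: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()


def _parse_region(region: str):
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, None, None
    start, _, end = span.partition("-")
    return chrom, int(start), int(end)


def read_vcf(path, region: str | None = None) -> VariantTable:
    """Read a VCF (plain or bgzipped) into a :class:`VariantTable`.

    ``region`` restricts to a 1-based closed interval ``chrom`` or
    ``chrom:start-end`` (simple scan; no index required).  GT accepts
    ``/`` and ``|`` separators; absent AD or GQ entries become missing
    with the site otherwise retained.  Malformed records raise with the
    offending position.
    """
    want = _parse_region(region) if region else None
    recs, gts, ads, gqs = [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        n = len(samples)
        for rec in vf:
            if want is not None:
                chrom, start, end = want
                if rec.chrom != chrom:
                    continue
                if start is not None and not (start <= rec.pos <= end):
                    continue
            try:
                row, g, a, q = _parse_record(rec, n)
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(
                    f"malformed VCF record at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
            recs.append(row)
            gts.append(g)
            ads.append(a)
            gqs.append(q)

    variants = pd.DataFrame(
        recs, columns=["chrom", "pos", "variant_id", "ref", "alt", "multiallelic"]
    )
    shape = (len(recs), n)
    ad = (np.array(ads, dtype=np.int64).reshape(len(recs), n, 2)
          if recs else np.empty((0, n, 2), dtype=np.int64))
    return VariantTable(
        samples=samples,
        variants=variants,
        gt=np.array(gts, dtype=np.int8).reshape(shape) if recs else np.empty(shape, np.int8),
        ad_ref=ad[:, :, 0],
        ad_alt=ad[:, :, 1],
        gq=np.array(gqs, dtype=np.int16).reshape(shape) if recs else np.empty(shape, np.int16),
    )


def _parse_record(rec, n):
    alts = rec.alts or ()
    multi = len(alts) != 1
    alt = ",".join(a or "." for a in alts) if alts else "."
    vid = rec.id or f"{rec.chrom}_{rec.pos}"
    row = (rec.chrom, rec.pos, vid, rec.ref, alt, multi)

    g = np.full(n, MISSING, dtype=np.int8)
    a = np.full((n, 2), MISSING, dtype=np.int64)
    q = np.full(n, MISSING, dtype=np.int16)
    if not multi:
        for j, name in enumerate(rec.samples):
            s = rec.samples[name]
            alleles = s.get("GT")
            if alleles is not None and None not in alleles and len(alleles) == 2:
                if not set(alleles) <= {0, 1}:
                    raise ValueError(f"GT allele index out of range in sample {name}")
                g[j] = sum(alleles)
            ad = s.get("AD")
            if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
                a[j] = (ad[0], ad[1])
            gq = s.get("GQ")
            if gq is not None:
                q[j] = min(int(gq), GQ_CAP)
    return row, g, a, q


def filter_complete_biallelic(table: VariantTable):
    """Keep biallelic variants with complete GT and AD in every sample.

    Returns the filtered table and a report dict with the number of
    variants removed per reason (``multiallelic`` first; remaining sites
    with any missing GT or AD count as ``incomplete``) plus the counts
    of input and surviving variants.
    """
    multi = table.variants["multiallelic"].to_numpy(dtype=bool)
    complete = (
        (table.gt != MISSING).all(axis=1)
        & (table.ad_ref != MISSING).all(axis=1)
        & (table.ad_alt != MISSING).all(axis=1)
    )
    keep = ~multi & complete
    report = {
        "n_input": int(table.n_variants),
        "multiallelic": int(multi.sum()),
        "incomplete": int((~multi & ~complete).sum()),
        "n_kept": int(keep.sum()),
    }
    out = VariantTable(
        samples=list(table.samples),
        variants=table.variants.loc[keep].reset_index(drop=True),
        gt=table.gt[keep],
        ad_ref=table.ad_ref[keep],
        ad_alt=table.ad_alt[keep],
        gq=table.gq[keep],
    )
    return out, report


def bundle_to_table(bundle: StudyBundle) -> VariantTable:
    """Materialise a simulated bundle as a :class:`VariantTable`,
    calling genotypes from the simulated counts (flat prior, standard
    caller error model)."""
    gt, gq = call_genotypes(bundle.ref_counts, bundle.alt_counts)
    variants = pd.DataFrame({
        "chrom": bundle.config.chrom,
        "pos": bundle.pos,
        "variant_id": bundle.variant_ids,
        "ref": bundle.ref_alleles,
        "alt": bundle.alt_alleles,
        "multiallelic": False,
    })
    return VariantTable(
        samples=bundle.sample_ids,
        variants=variants,
        gt=gt.astype(np.int8),
        ad_ref=bundle.ref_counts,
        ad_alt=bundle.alt_counts,
        gq=gq.astype(np.int16),
    )


def write_vcf(data, path) -> None:
    """Write a :class:`VariantTable` or simulated bundle as VCF 4.2.

    FORMAT is GT:AD:GQ; records are sorted by (chrom, pos); GQ is
    capped at 99; missing genotypes are written as ``./.``.  The output
    round-trips through :func:`read_vcf` on GT, AD and GQ.
    """
    table = bundle_to_table(data) if isinstance(data, StudyBundle) else data

    header = pysam.VariantHeader()
    header.add_line('##source=adassoc')
    for chrom in pd.unique(table.variants["chrom"].astype(str)):
        end = int(table.variants.loc[table.variants["chrom"].astype(str) == chrom, "pos"].max()) + 1000
        header.contigs.add(chrom, length=end)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths for the ref and alt alleles in the order listed")
    header.formats.add("GQ", 1, "Integer", "Genotype Quality")
    for s in table.samples:
        header.add_sample(s)

    order = table.variants.sort_values(["chrom", "pos"], kind="stable").index
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            row = table.variants.loc[i]
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]) - 1 + len(row["ref"]),
                alleles=(row["ref"], *str(row["alt"]).split(",")),
                id=row["variant_id"],
            )
            for j, s in enumerate(table.samples):
                g = int(table.gt[i, j])
                rec.samples[s]["GT"] = _dosage_to_gt(g)
                if table.ad_ref[i, j] != MISSING and table.ad_alt[i, j] != MISSING:
                    rec.samples[s]["AD"] = (int(table.ad_ref[i, j]), int(table.ad_alt[i, j]))
                if table.gq[i, j] != MISSING:
                    rec.samples[s]["GQ"] = int(min(table.gq[i, j], GQ_CAP))
            out.write(rec)


def _dosage_to_gt(g: int):
    if g == 0:
        return (0, 0)
    if g == 1:
        return (0, 1)
    if g == 2:
        return (1, 1)
    return (None, None)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV with header columns sample_id, phenotype."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "phenotype"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks required column(s): {sorted(missing)}")
    return df[["sample_id", "phenotype"]].astype({"sample_id": str})


def write_phenotypes(sample_ids, phenotypes, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "phenotype": phenotypes}).to_csv(
        path, sep="\t", index=False
    )


def write_filter_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
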