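"""SNP filtering, region merging/annotation and SNV-region intersection.

These are in-memory transformations between the readers in
:mod:`smurf.genomic_io` and the statistics in :mod:`smurf.enrichment_stats`.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .types import (
    DISTAL,
    PROMOTER,
    Region,
    RegionMutationSummary,
    SnpCatalogueEntry,
    SnvRecord,
)

logger = logging.getLogger("smurf")

SNP_FILTER_MODES = ("none", "all", "maf")

#: Known SNPs with MAF above this are presumed germline and removed in "maf"
#: mode; rarer matches are kept as possibly acquired variants.
MAF_CUTOFF = 0.01


def filter_known_snps(
    snvs: Sequence[SnvRecord],
    catalogue: Iterable[SnpCatalogueEntry],
    mode: str = "none",
) -> tuple[list[SnvRecord], int]:
    """Remove SNVs matching the known-polymorphism catalogue.

    Matching is by position only (chrom, pos0); the catalogue carries no
    allele information at the BED level.

    mode="none"  keep everything;
    mode="all"   drop any SNV at a catalogued position;
    mode="maf"   drop only matches whose catalogue MAF exceeds 1% — rare
                 polymorphism positions (or entries without a MAF) are kept,
                 preserving potentially interesting acquired variants.

    Returns (retained SNVs, number removed).
    """
    if mode not in SNP_FILTER_MODES:
        raise ValueError(f"unknown SNP filter mode {mode!r}; expected one of {SNP_FILTER_MODES}")
    if mode == "none":
        return list(snvs), 0

    if mode == "all":
        drop = {(e.chrom, e.pos0) for e in catalogue}
    else:
        drop = {
            (e.chrom, e.pos0)
            for e in catalogue
            if e.maf is not None and e.maf > MAF_CUTOFF
        }
    kept = [rec for rec in snvs if (rec.chrom, rec.pos0) not in drop]
    n_removed = len(snvs) - len(kept)
    if n_removed:
        logger.info("snp_filter_mode=%s snps_removed=%d", mode, n_removed)
    return kept, n_removed


def merge_regions(regions: Sequence[Region]) -> list[Region]:
    """Merge overlapping or book-ended intervals per chromosome.

    Output is sorted by (chrom, start0); gene names are unioned across merged
    members and a merged interval containing any promoter bp stays promoter.
    Idempotent: merging a merged catalogue is a no-op.
    """
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    merged: list[Region] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start0, r.end0))
        cur_s, cur_e = rs[0].start0, rs[0].end0
        cur_genes: set[str] = set(rs[0].gene_names)
        cur_promoter = rs[0].annotation == PROMOTER
        for r in rs[1:]:
            if r.start0 <= cur_e:  # overlap or shared boundary
                cur_e = max(cur_e, r.end0)
                cur_genes.update(r.gene_names)
                cur_promoter = cur_promoter or r.annotation == PROMOTER
            else:
                merged.append(_make_region(chrom, cur_s, cur_e, cur_promoter, cur_genes))
                cur_s, cur_e = r.start0, r.end0
                cur_genes = set(r.gene_names)
                cur_promoter = r.annotation == PROMOTER
        merged.append(_make_region(chrom, cur_s, cur_e, cur_promoter, cur_genes))
    return merged


def _make_region(chrom: str, s: int, e: int, promoter: bool, genes: set[str]) -> Region:
    if promoter or genes:
        return Region(chrom, s, e, annotation=PROMOTER, gene_names=tuple(sorted(genes)))
    return Region(chrom, s, e)


def annotate_regions(
    regions: Sequence[Region], promoters: Sequence[Region]
) -> list[Region]:
    """Classify each region as promoter or distal.

    A region overlapping at least 1 bp of any promoter window becomes a
    promoter region carrying the union of the overlapping windows' gene
    symbols; otherwise it is a distal regulatory element. Intervals are
    half-open, so abutting features do not count as overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for p in promoters:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start0, p.end0, p.gene_names)

    annotated: list[Region] = []
    for r in regions:
        tree = trees.get(r.chrom)
        hits = tree.overlap(r.start0, r.end0) if tree is not None else ()
        if hits:
            genes = sorted({g for iv in hits for g in iv.data})
            annotated.append(
                Region(r.chrom, r.start0, r.end0, annotation=PROMOTER, gene_names=tuple(genes))
            )
        else:
            annotated.append(Region(r.chrom, r.start0, r.end0, annotation=DISTAL))
    return annotated


def _check_disjoint(regions: Sequence[Region]) -> None:
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start0)
        for a, b in zip(rs, rs[1:]):
            if b.start0 < a.end0:
                raise ValueError(
                    f"overlapping regions passed to intersection: "
                    f"{a.region_id} and {b.region_id} (merge the catalogue first)"
                )


def intersect_snvs_regions(
    snvs: Sequence[SnvRecord], regions: Sequence[Region]
) -> tuple[list[RegionMutationSummary], int]:
    """Assign every SNV to exactly one region of a merged catalogue.

    Regions must be non-overlapping (run :func:`merge_regions` first); a
    violation raises. Returns one summary per region — including regions with
    zero mutations — in catalogue order, plus the count of SNVs falling
    outside every region. Positions are half-open: an SNV at ``end0`` is
    outside.
    """
    _check_disjoint(regions)
    trees: dict[str, IntervalTree] = {}
    for idx, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start0, r.end0, idx)

    counts = [0] * len(regions)
    samples: list[set[str]] = [set() for _ in regions]
    n_outside = 0
    for rec in snvs:
        tree = trees.get(rec.chrom)
        hits = tree[rec.pos0] if tree is not None else ()
        if hits:
            idx = next(iter(hits)).data  # disjoint catalogue: at most one hit
            counts[idx] += 1
            samples[idx].add(rec.sample_id)
        else:
            n_outside += 1

    summaries = [
        RegionMutationSummary(region=r, n_mutations=counts[i], sample_ids=frozenset(samples[i]))
        for i, r in enumerate(regions)
    ]
    return summaries, n_outside


def cohort_summary(
    per_sample_totals: Mapping[str, int],
    summaries: Sequence[RegionMutationSummary],
    per_sample_in_regions: Optional[Mapping[str, int]] = None,
):
    """Per-sample SNV totals and the fraction landing inside the catalogue.

    ``per_sample_totals`` counts each sample's retained SNVs (after SNP
    filtering and deduplication). ``per_sample_in_regions`` may be supplied
    directly; otherwise it is reconstructed from the region summaries' sample
    sets only when every region holds at most one SNV per sample, so callers
    normally pass it. Samples with zero SNVs get an undefined (NaN)
    percentage, not 0. Returns a pandas DataFrame indexed by sample_id with
    columns n_snvs, n_in_regions, pct_in_regions, plus the cohort mean
    percentage over samples with at least one SNV.
    """
    import math

    import pandas as pd

    if per_sample_in_regions is None:
        inside: dict[str, int] = {s: 0 for s in per_sample_totals}
        for summ in summaries:
            for s in summ.sample_ids:
                inside[s] = inside.get(s, 0) + 1
    else:
        inside = dict(per_sample_in_regions)

    rows = []
    for sample in sorted(per_sample_totals):
        total = per_sample_totals[sample]
        n_in = inside.get(sample, 0)
        pct = 100.0 * n_in / total if total > 0 else math.nan
        rows.append((sample, total, n_in, pct))
    df = pd.DataFrame(rows, columns=["sample_id", "n_snvs", "n_in_regions", "pct_in_regions"])
    df = df.set_index("sample_id")
    mean_pct = float(df["pct_in_regions"].mean())  # NaNs excluded
    return df, mean_pct
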