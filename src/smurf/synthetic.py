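"""Synthetic cohorts with known ground truth, and matched peak sampling.

The generator emulates the statistical structure of a whole-genome somatic
SNV cohort intersected with a chromatin-accessibility peak catalogue:
non-overlapping regions placed uniformly on synthetic chromosomes, and
per-region per-sample mutation counts drawn as Binomial(region_length, rate)
where the rate is a per-bp per-sample background, multiplied by a fold factor
for spiked (truly enriched) regions and by a sample-level multiplier for
hypermutated samples. It emits the exact file formats the readers consume,
plus a ground-truth table, and is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import PROMOTER, Region, SnpCatalogueEntry, SnvRecord


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 30_000_000, "chr2": 20_000_000}


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a sparse null cohort in the regime of real liver-cancer
    whole genomes intersected with accessibility peaks (~1e-6 mutations per
    bp per sample inside peaks): 20 samples, 2000 regions of 200-1000 bp, no
    enrichment, no hypermutated samples.
    """

    n_samples: int = 20
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_regions: int = 2000
    region_length_range: tuple[int, int] = (200, 1000)
    background_rate: float = 1e-6
    n_enriched: int = 0
    fold_enrichment: float = 1.0
    hypermutated_samples: tuple[int, float] = (0, 1.0)
    snp_density: float = 1e-5
    promoter_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_regions < 1:
            raise ValueError("need at least one sample and one region")
        if self.n_enriched > self.n_regions:
            raise ValueError("n_enriched exceeds n_regions")
        if self.fold_enrichment < 1.0:
            raise ValueError("fold_enrichment must be >= 1")
        lo, hi = self.region_length_range
        if not (1 <= lo <= hi):
            raise ValueError("bad region_length_range")
        if not (0.0 <= self.background_rate <= 1.0):
            raise ValueError("background_rate must be in [0, 1]")
        n_hyper, mult = self.hypermutated_samples
        if n_hyper > self.n_samples or n_hyper < 0 or mult < 0:
            raise ValueError("bad hypermutated_samples")


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort plus writers for the on-disk fixture."""

    spec: SyntheticCohortSpec
    regions: list[Region]
    snvs_by_sample: dict[str, list[SnvRecord]]
    snp_catalogue: list[SnpCatalogueEntry]
    promoters: list[Region]
    truth: pd.DataFrame  # region_id, is_enriched, true_fold

    @property
    def sample_ids(self) -> list[str]:
        return list(self.snvs_by_sample)

    @property
    def all_snvs(self) -> list[SnvRecord]:
        return [rec for sample in self.snvs_by_sample.values() for rec in sample]

    @property
    def enriched_region_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["is_enriched"], "region_id"])

    def write(self, out_dir) -> dict[str, Path]:
        """Write regions.bed, snvs/<sample>.bed, snp_catalogue.bed,
        promoters.bed and ground_truth.tsv. Byte-identical for equal spec."""
        out = Path(out_dir)
        (out / "snvs").mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["regions"] = out / "regions.bed"
        paths["regions"].write_text(
            "".join(f"{r.chrom}\t{r.start0}\t{r.end0}\n" for r in self.regions)
        )
        for sample, recs in self.snvs_by_sample.items():
            p = out / "snvs" / f"{sample}.bed"
            p.write_text(
                "".join(
                    f"{v.chrom}\t{v.pos0}\t{v.pos0 + 1}\t{sample}\n"
                    for v in sorted(recs, key=lambda v: (v.chrom, v.pos0))
                )
            )
            paths[f"snvs/{sample}"] = p
        paths["snp_catalogue"] = out / "snp_catalogue.bed"
        paths["snp_catalogue"].write_text(
            "".join(
                f"{e.chrom}\t{e.pos0}\t{e.pos0 + 1}\t"
                + ("." if e.maf is None else f"{e.maf:.6f}")
                + "\n"
                for e in self.snp_catalogue
            )
        )
        paths["promoters"] = out / "promoters.bed"
        paths["promoters"].write_text(
            "".join(
                f"{p.chrom}\t{p.start0}\t{p.end0}\t{','.join(p.gene_names)}\n"
                for p in self.promoters
            )
        )
        paths["truth"] = out / "ground_truth.tsv"
        paths["truth"].write_text(self.truth.to_csv(sep="\t", index=False))
        return paths

    def file_digests(self, out_dir) -> dict[str, str]:
        return {
            name: hashlib.sha256(p.read_bytes()).hexdigest()
            for name, p in self.write(out_dir).items()
        }


def _allocate_counts(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder split of `total` proportional to `weights`."""
    w = np.asarray(weights, dtype=float)
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def _place_regions(rng: np.random.Generator, spec: SyntheticCohortSpec) -> list[Region]:
    chroms = sorted(spec.chrom_sizes)
    per_chrom = _allocate_counts(spec.n_regions, [spec.chrom_sizes[c] for c in chroms])
    lo, hi = spec.region_length_range
    regions: list[Region] = []
    for chrom, n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        size = spec.chrom_sizes[chrom]
        lengths = rng.integers(lo, hi + 1, size=n_c)
        total_len = int(lengths.sum())
        free = size - total_len - n_c
        if free < 0:
            raise ValueError(
                f"cannot place {n_c} disjoint regions totalling {total_len} bp "
                f"on {chrom} of size {size}"
            )
        # Sorted random offsets plus a forced 1-bp gap keep regions disjoint
        # and non-book-ended (so merging the catalogue is a no-op).
        base = np.sort(rng.integers(0, free + 1, size=n_c))
        starts = base + np.arange(n_c) + np.concatenate(([0], np.cumsum(lengths[:-1])))
        for s, ln in zip(starts, lengths):
            regions.append(Region(chrom, int(s), int(s + ln)))
    return regions


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort from the spec.

    All randomness flows from ``spec.seed`` through named child streams, so
    the components (regions, SNVs, SNP catalogue, promoters) are individually
    reproducible. SNV positions within a region are uniform without
    replacement per sample; the same position may recur across samples.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_regions, rng_enrich, rng_snvs, rng_snps, rng_prom = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    regions = _place_regions(rng_regions, spec)
    n = len(regions)
    lengths = np.array([r.length for r in regions])

    fold = np.ones(n)
    enriched_idx = np.array([], dtype=int)
    if spec.n_enriched:
        enriched_idx = np.sort(rng_enrich.choice(n, size=spec.n_enriched, replace=False))
        fold[enriched_idx] = spec.fold_enrichment

    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    n_hyper, hyper_mult = spec.hypermutated_samples
    sample_mult = np.ones(spec.n_samples)
    if n_hyper:
        sample_mult[-n_hyper:] = hyper_mult  # last samples are the hypermutated ones

    rate = np.clip(spec.background_rate * fold[:, None] * sample_mult[None, :], 0.0, 1.0)
    counts = rng_snvs.binomial(lengths[:, None], rate)

    snvs_by_sample: dict[str, list[SnvRecord]] = {s: [] for s in sample_ids}
    for r_idx, s_idx in zip(*np.nonzero(counts)):
        c = int(counts[r_idx, s_idx])
        region = regions[r_idx]
        offsets = rng_snvs.choice(region.length, size=c, replace=False)
        for off in np.sort(offsets):
            snvs_by_sample[sample_ids[s_idx]].append(
                SnvRecord(region.chrom, region.start0 + int(off), sample_ids[s_idx])
            )

    snp_catalogue: list[SnpCatalogueEntry] = []
    genome_bp = sum(spec.chrom_sizes.values())
    n_snps = int(round(spec.snp_density * genome_bp))
    if n_snps:
        chroms = sorted(spec.chrom_sizes)
        per_chrom = _allocate_counts(n_snps, [spec.chrom_sizes[c] for c in chroms])
        for chrom, n_c in zip(chroms, per_chrom):
            pos = np.sort(rng_snps.integers(0, spec.chrom_sizes[chrom], size=n_c))
            mafs = rng_snps.uniform(0.0, 0.5, size=n_c)
            missing = rng_snps.random(n_c) < 0.1  # catalogues rarely report every MAF
            for p, m, miss in zip(pos, mafs, missing):
                snp_catalogue.append(
                    SnpCatalogueEntry(chrom, int(p), None if miss else float(m))
                )

    promoters: list[Region] = []
    n_prom = int(round(spec.promoter_fraction * n))
    if n_prom:
        prom_idx = np.sort(rng_prom.choice(n, size=n_prom, replace=False))
        for j, r_idx in enumerate(prom_idx):
            region = regions[r_idx]
            width = min(500, region.length)
            promoters.append(
                Region(
                    region.chrom,
                    region.start0,
                    region.start0 + width,
                    annotation=PROMOTER,
                    gene_names=(f"GENE{j + 1:04d}",),
                )
            )

    is_enriched = np.zeros(n, dtype=bool)
    is_enriched[enriched_idx] = True
    truth = pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "is_enriched": is_enriched,
            "true_fold": np.where(is_enriched, spec.fold_enrichment, 1.0),
        }
    )
    return SyntheticCohort(
        spec=spec,
        regions=regions,
        snvs_by_sample=snvs_by_sample,
        snp_catalogue=snp_catalogue,
        promoters=promoters,
        truth=truth,
    )


def sample_matched_peaks(
    candidate_peaks: Sequence[Region],
    reference_peaks: Sequence[Region],
    n_iterations: int,
    seed: int,
    n_bins: int = 10,
) -> list[list[Region]]:
    """Draw peak subsets matched to a reference set in number and length.

    Used to compare catalogues fairly: a larger candidate peak set is
    repeatedly down-sampled (without replacement within an iteration) to the
    reference set's size and length distribution. Reference lengths are
    binned into ``n_bins`` quantile bins (deciles by default) and the same
    per-bin counts are drawn from the candidates.
    """
    if len(candidate_peaks) < len(reference_peaks):
        raise ValueError(
            f"candidate set ({len(candidate_peaks)}) smaller than reference "
            f"({len(reference_peaks)})"
        )
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    ref_lengths = np.array([r.length for r in reference_peaks])
    cand_lengths = np.array([r.length for r in candidate_peaks])
    # Duplicate quantile edges (heavily tied length distributions) are
    # collapsed; candidates outside the reference length range are never
    # eligible, so a constant-length reference draws only that length.
    uniq = np.unique(np.quantile(ref_lengths, np.linspace(0, 1, n_bins + 1)))
    if uniq.size == 1:
        n_eff = 1
        ref_bins = np.zeros(ref_lengths.size, dtype=int)
        cand_bins = np.where(cand_lengths == uniq[0], 0, -1)
        bounds = [(uniq[0], uniq[0])]
    else:
        inner = uniq[1:-1]
        n_eff = uniq.size - 1
        ref_bins = np.searchsorted(inner, ref_lengths, side="right")
        cand_bins = np.searchsorted(inner, cand_lengths, side="right")
        cand_bins[(cand_lengths < uniq[0]) | (cand_lengths > uniq[-1])] = -1
        bounds = [(uniq[b], uniq[b + 1]) for b in range(n_eff)]

    need = np.bincount(ref_bins, minlength=n_eff)
    pools = [np.flatnonzero(cand_bins == b) for b in range(n_eff)]
    for b in range(n_eff):
        if need[b] > len(pools[b]):
            raise ValueError(
                f"length bin {b} ([{bounds[b][0]:.0f}, {bounds[b][1]:.0f}] bp) needs "
                f"{need[b]} peaks but only {len(pools[b])} candidates fall in it"
            )

    iterations: list[list[Region]] = []
    for child in np.random.SeedSequence(seed).spawn(n_iterations):
        rng = np.random.default_rng(child)
        chosen: list[int] = []
        for b in range(n_eff):
            if need[b]:
                chosen.extend(rng.choice(pools[b], size=need[b], replace=False))
        iterations.append([candidate_peaks[i] for i in sorted(chosen)])
    return iterations
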