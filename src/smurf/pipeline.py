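"""End-to-end orchestration: read -> filter -> merge -> annotate -> intersect
-> rates -> binomial test -> FDR -> rate threshold -> significance -> write.

:func:`analyse` is the in-memory core working on parsed objects;
:func:`run_pipeline` wraps it with file I/O and run metadata for the CLI.
Stage counts are logged as ``key=value`` pairs and returned on the result so
they can be reconciled: snvs_read = duplicates_removed + snps_removed +
snvs_in_regions + snvs_outside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import enrichment_stats as stats
from . import genomic_io as gio
from . import snv_processing as proc
from .types import (
    DISTAL,
    EnrichmentResult,
    Region,
    SampleRateTable,
    SnpCatalogueEntry,
    SnvRecord,
    ThresholdResult,
)

logger = logging.getLogger("smurf")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """File-level configuration of one run."""

    snv_paths: list[str]
    regions_path: str
    out_dir: str
    snv_format: str = "bed"  # "bed" or "vcf"
    sample_column: object = "from-filename"  # int (1-based) or "from-filename"
    snp_catalogue_path: Optional[str] = None
    snp_filter_mode: str = "none"
    maf_column: int = 4
    promoters_path: Optional[str] = None
    gtf_path: Optional[str] = None
    upstream: int = 2000
    downstream: int = 500
    background_mode: str = "allsamples"
    trials_convention: str = "cohort"
    q_cutoff: float = 0.05
    normalize_chrom: Optional[str] = None
    scatter_all: bool = False
    plot: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.q_cutoff < 1.0):
            raise ValueError("q_cutoff must lie in (0, 1)")
        if self.snv_format not in ("bed", "vcf"):
            raise ValueError(f"unknown SNV format {self.snv_format!r}")
        if self.promoters_path and self.gtf_path:
            raise ValueError("give either a promoter BED or a GTF, not both")


@dataclass
class PipelineResult:
    """Everything a run computed, before or after writing files."""

    results: list[EnrichmentResult]
    threshold: Optional[ThresholdResult]
    rate_table: Optional[SampleRateTable]
    counts: dict[str, int]
    sample_summary: pd.DataFrame
    mean_pct_in_regions: float
    merged_regions: list[Region] = dc_field(default_factory=list)

    @property
    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.significant]


def analyse(
    snvs: Sequence[SnvRecord],
    regions: Sequence[Region],
    promoters: Sequence[Region] = (),
    snp_catalogue: Sequence[SnpCatalogueEntry] = (),
    *,
    snp_filter_mode: str = "none",
    background_mode: str = "allsamples",
    trials_convention: str = "cohort",
    q_cutoff: float = 0.05,
    cohort_samples: Optional[Sequence[str]] = None,
) -> PipelineResult:
    """Run the statistical pipeline on parsed objects.

    ``cohort_samples`` fixes the cohort (so samples with zero retained SNVs
    still contribute rate 0 to the background); by default the cohort is the
    set of sample ids observed in the input.

    ``trials_convention`` sets the binomial trial count per region:
    "cohort" uses region_length x cohort size in both background modes (the
    region is surveyed in every sample, so each sample-bp is a trial);
    "mutated" shrinks it to region_length x number of mutated samples in
    regionsamples mode.
    """
    if trials_convention not in stats.TRIALS_CONVENTIONS:
        raise ValueError(f"unknown trials convention {trials_convention!r}")
    counts: dict[str, int] = {}
    counts["snvs_read"] = len(snvs)
    counts["regions_input"] = len(regions)

    deduped, n_dup = gio.dedupe_snvs(list(snvs))
    counts["duplicates_removed"] = n_dup

    retained, n_snp = proc.filter_known_snps(deduped, snp_catalogue, mode=snp_filter_mode)
    counts["snps_removed"] = n_snp

    merged = proc.merge_regions(regions) if regions else []
    counts["regions_merged"] = len(merged)
    if promoters:
        merged = proc.annotate_regions(merged, promoters)
    else:
        merged = [Region(r.chrom, r.start0, r.end0, annotation=DISTAL) for r in merged]

    summaries, n_outside = proc.intersect_snvs_regions(retained, merged)
    n_inside = sum(s.n_mutations for s in summaries)
    counts["snvs_in_regions"] = n_inside
    counts["snvs_outside"] = n_outside

    cohort = sorted(set(cohort_samples) if cohort_samples else {v.sample_id for v in retained})
    per_sample_total = {s: 0 for s in cohort}
    per_sample_inside = {s: 0 for s in cohort}
    for v in retained:
        if v.sample_id in per_sample_total:
            per_sample_total[v.sample_id] += 1
    # Per-sample in-region counts: direct lookup against the merged catalogue
    # (the summaries only keep which samples are mutated, not how often).
    region_index = _RegionIndex(merged)
    for v in retained:
        if v.sample_id in per_sample_inside and region_index.covers(v.chrom, v.pos0):
            per_sample_inside[v.sample_id] += 1

    sample_summary, mean_pct = proc.cohort_summary(
        per_sample_total, summaries, per_sample_inside
    )

    total_bp = sum(r.length for r in merged)
    rate_table: Optional[SampleRateTable] = None
    results: list[EnrichmentResult] = []
    threshold: Optional[ThresholdResult] = None

    if merged and cohort:
        rate_table = stats.per_sample_rates(per_sample_inside, total_bp)
        n_cohort = len(cohort)
        tested = [s for s in summaries if s.n_mutations > 0]
        p_values = []
        for summ in tested:
            bg = stats.background_rate(background_mode, rate_table, summ.sample_ids)
            n_for_trials = (
                n_cohort
                if trials_convention == "cohort" or background_mode == "allsamples"
                else summ.n_unique_samples
            )
            p = stats.binomial_enrichment_test(
                summ.n_mutations, summ.region.length, n_for_trials, bg
            )
            p_values.append((summ, bg, summ.region.length * n_for_trials, p))

        # The FDR family is every region in the catalogue: a zero-mutation
        # region's exact binomial p-value is 1, and it enters BH at that
        # value. Restricting the family to mutated regions would condition
        # every member on k >= 1 — in a sparse cohort those conditional
        # p-values are all small, and BH over them alone calls essentially
        # every mutated region significant under the null.
        tested_stats = {id(summ): (bg, n_trials, p) for summ, bg, n_trials, p in p_values}
        full_p = [tested_stats.get(id(s), (None, None, 1.0))[2] for s in summaries]
        full_q = stats.adjust_multiple_testing(full_p)
        for summ, p, q in zip(summaries, full_p, full_q):
            bg, n_trials, _ = tested_stats.get(id(summ), (None, None, 1.0))
            results.append(
                EnrichmentResult(
                    region=summ.region,
                    summary=summ,
                    background_rate=bg,
                    n_trials=n_trials,
                    p_value=p,
                    q_value=float(q),
                    tested=id(summ) in tested_stats,
                )
            )
        if tested:
            threshold = stats.inflection_threshold([s.region_rate for s in tested])
        stats.call_significant(results, q_cutoff=q_cutoff, threshold=threshold)
    else:
        results = [
            EnrichmentResult(region=s.region, summary=s, background_rate=None, n_trials=None)
            for s in summaries
        ]

    counts["regions_tested"] = sum(r.tested for r in results)
    counts["regions_significant"] = sum(r.significant for r in results)
    for key, val in counts.items():
        logger.info("%s=%d", key, val)
    return PipelineResult(
        results=results,
        threshold=threshold,
        rate_table=rate_table,
        counts=counts,
        sample_summary=sample_summary,
        mean_pct_in_regions=mean_pct,
        merged_regions=merged,
    )


class _RegionIndex:
    """Point-in-catalogue lookup over a merged (disjoint) region list."""

    def __init__(self, regions: Sequence[Region]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[Region]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            rs = sorted(rs, key=lambda r: r.start0)
            self._starts[chrom] = np.array([r.start0 for r in rs])
            self._ends[chrom] = np.array([r.end0 for r in rs])

    def covers(self, chrom: str, pos0: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]


def scatter_data(results: Sequence[EnrichmentResult], include_all: bool = False) -> pd.DataFrame:
    """Table behind the -log10(q) vs unique-sample-count scatter.

    One row per significant region (or per tested region with
    ``include_all``); the annotation column is the promoter/distal
    two-class colour key.
    """
    rows = []
    for r in results:
        if r.significant or (include_all and r.tested):
            rows.append(
                (
                    r.region.region_id,
                    r.summary.n_unique_samples,
                    -math.log10(r.q_value),
                    r.region.annotation or "",
                )
            )
    return pd.DataFrame(
        rows, columns=["region_id", "n_unique_samples", "minus_log10_q", "annotation"]
    )


def _read_inputs(config: RunConfig):
    stage = "read_regions"
    try:
        regions = gio.read_regions_bed(config.regions_path, normalize_chrom=config.normalize_chrom)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage={stage}: {exc}") from exc

    stage = "read_snvs"
    snvs: list[SnvRecord] = []
    cohort: set[str] = set()
    try:
        for path in config.snv_paths:
            if config.snv_format == "vcf":
                sample = Path(path).stem
                recs = gio.read_snvs_vcf(
                    path, sample, normalize_chrom=config.normalize_chrom, dedup=False
                )
            else:
                recs = gio.read_snvs_bed(
                    path,
                    config.sample_column,
                    normalize_chrom=config.normalize_chrom,
                    dedup=False,
                )
                if config.sample_column == "from-filename":
                    cohort.add(Path(path).stem)
            snvs.extend(recs)
            cohort.update(r.sample_id for r in recs)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage={stage}: {exc}") from exc

    stage = "read_snp_catalogue"
    catalogue: list[SnpCatalogueEntry] = []
    if config.snp_catalogue_path:
        try:
            catalogue = gio.read_snp_catalogue(
                config.snp_catalogue_path,
                config.maf_column,
                normalize_chrom=config.normalize_chrom,
            )
        except (OSError, ValueError) as exc:
            raise PipelineError(f"stage={stage}: {exc}") from exc

    stage = "read_promoters"
    promoters: list[Region] = []
    try:
        if config.promoters_path:
            promoters = gio.read_promoters_bed(
                config.promoters_path, normalize_chrom=config.normalize_chrom
            )
        elif config.gtf_path:
            promoters = gio.derive_promoter_catalogue(
                config.gtf_path,
                config.upstream,
                config.downstream,
                normalize_chrom=config.normalize_chrom,
            )
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage={stage}: {exc}") from exc

    return snvs, regions, promoters, catalogue, sorted(cohort)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute a full file-to-file run.

    All outputs are written only after every stage has succeeded, so a
    failing run leaves no partial files. Succeeds (and writes all files)
    even when zero regions are significant.
    """
    snvs, regions, promoters, catalogue, cohort = _read_inputs(config)

    try:
        result = analyse(
            snvs,
            regions,
            promoters,
            catalogue,
            snp_filter_mode=config.snp_filter_mode,
            background_mode=config.background_mode,
            trials_convention=config.trials_convention,
            q_cutoff=config.q_cutoff,
            cohort_samples=cohort or None,
        )
    except ValueError as exc:
        raise PipelineError(f"stage=analyse: {exc}") from exc

    stage = "write_outputs"
    try:
        out = Path(config.out_dir)
        paths = gio.write_outputs(result.results, out)
        if config.scatter_all:
            paths["scatter"].write_text(
                scatter_data(result.results, include_all=True).to_csv(sep="\t", index=False)
            )
        (out / "sample_summary.tsv").write_text(
            result.sample_summary.to_csv(sep="\t")
        )
        (out / "run_metadata.txt").write_text(_run_metadata(config, result))
        if config.plot:
            _maybe_plot(result, out / "scatter.png")
    except OSError as exc:
        raise PipelineError(f"stage={stage}: {exc}") from exc
    return result


def _run_metadata(config: RunConfig, result: PipelineResult) -> str:
    lines = {
        "background_mode": config.background_mode,
        "trials_convention": config.trials_convention,
        "snp_filter_mode": config.snp_filter_mode,
        "q_cutoff": repr(config.q_cutoff),
        "promoter_window_upstream": config.upstream,
        "promoter_window_downstream": config.downstream,
        "chrom_normalization": config.normalize_chrom or "off",
        "threshold_rate": repr(result.threshold.threshold_rate) if result.threshold else "NA",
        "rank_at_inflection": result.threshold.rank_at_inflection if result.threshold else "NA",
        "n_samples": result.rate_table.n_samples if result.rate_table else 0,
        "total_region_bp": result.rate_table.total_region_bp if result.rate_table else 0,
        "mean_pct_snvs_in_regions": f"{result.mean_pct_in_regions:.4f}",
    }
    lines.update(result.counts)
    return "".join(f"{k}={v}\n" for k, v in lines.items())


def _maybe_plot(result: PipelineResult, path: Path) -> None:
    """Render the scatter figure if a plotting backend is available."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        logger.warning("plot_skipped=no_matplotlib")
        return
    df = scatter_data(result.results)
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, color in (("promoter", "tab:red"), ("distal", "tab:blue")):
        sub = df[df["annotation"] == label]
        ax.scatter(sub["n_unique_samples"], sub["minus_log10_q"], s=12, label=label, color=color)
    ax.set_xlabel("unique mutated samples")
    ax.set_ylabel("-log10(q)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
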