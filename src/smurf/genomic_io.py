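"""Reading and writing of genomic inputs and result files.

Input formats: BED3+ region catalogues, BED4+ per-sample SNVs, VCF 4.x,
Gencode-dialect GTF for promoter derivation, and dbSNP-style BED catalogues
with a minor-allele-frequency column. Everything is converted to 0-based
half-open coordinates on read.
"""

from __future__ import annotations

import logging
import math
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .types import DISTAL, PROMOTER, EnrichmentResult, Region, SnpCatalogueEntry, SnvRecord

logger = logging.getLogger("smurf")

PathLike = Union[str, Path]

#: Column order of the main results table written by :func:`write_outputs`.
RESULT_COLUMNS = [
    "chrom",
    "start0",
    "end0",
    "region_id",
    "annotation",
    "gene_names",
    "n_mutations",
    "n_unique_samples",
    "region_rate",
    "background_rate",
    "p_value",
    "q_value",
    "passes_rate_threshold",
    "significant",
    "tested",
]


class GenomicIOError(ValueError):
    """Malformed or inconsistent genomic input."""


def _normalize_chrom(chrom: str, normalize: Optional[str]) -> str:
    if normalize is None:
        return chrom
    if normalize == "add-chr":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    if normalize == "strip-chr":
        return chrom[3:] if chrom.startswith("chr") else chrom
    raise ValueError(f"unknown chromosome normalization {normalize!r}")


def _data_lines(path: PathLike):
    """Yield (line_number, stripped_line), skipping comments and blanks."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line


def dedupe_snvs(snvs: Sequence[SnvRecord]) -> tuple[list[SnvRecord], int]:
    """Drop records sharing (chrom, pos0, sample_id), keeping first occurrence.

    Duplicate calls would double-count in the binomial numerator. Returns the
    retained records (input order) and the number removed.
    """
    seen: set[tuple] = set()
    kept: list[SnvRecord] = []
    for rec in snvs:
        # alleles enter the key so the split records of a multi-allelic VCF
        # site survive; BED records (no alleles) dedupe on position alone
        key = (rec.chrom, rec.pos0, rec.sample_id, rec.ref, rec.alt)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    n_dup = len(snvs) - len(kept)
    if n_dup:
        logger.info("duplicates_removed=%d", n_dup)
    return kept, n_dup


def read_snvs_bed(
    path: PathLike,
    sample_column: Union[int, str] = "from-filename",
    *,
    normalize_chrom: Optional[str] = None,
    dedup: bool = True,
) -> list[SnvRecord]:
    """Read single-nucleotide variants from a BED file.

    Each line must describe a 1-bp interval (``end - start == 1``); longer
    intervals are rejected as non-SNVs. ``sample_column`` is a 1-based column
    index holding the sample identifier, or ``"from-filename"`` to use the
    file stem for every record (one file per sample).
    """
    if sample_column == "from-filename":
        stem_sample: Optional[str] = Path(path).stem
        col_idx: Optional[int] = None
    elif isinstance(sample_column, int) and sample_column >= 4:
        stem_sample = None
        col_idx = sample_column - 1
    else:
        raise ValueError(
            f"sample_column must be 'from-filename' or a column index >= 4, "
            f"got {sample_column!r}"
        )

    records: list[SnvRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise GenomicIOError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError as exc:
            raise GenomicIOError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end - start != 1:
            raise GenomicIOError(
                f"{path}:{lineno}: interval length {end - start} is not a "
                "single-nucleotide variant (expected end - start == 1)"
            )
        if stem_sample is not None:
            sample = stem_sample
        else:
            if col_idx >= len(fields):
                raise GenomicIOError(
                    f"{path}:{lineno}: missing sample column {col_idx + 1}"
                )
            sample = fields[col_idx]
            if not sample:
                raise GenomicIOError(f"{path}:{lineno}: empty sample identifier")
        records.append(
            SnvRecord(
                chrom=_normalize_chrom(fields[0], normalize_chrom),
                pos0=start,
                sample_id=sample,
            )
        )
    if dedup:
        records, _ = dedupe_snvs(records)
    return records


def read_snvs_vcf(
    path: PathLike,
    sample_id: str,
    *,
    normalize_chrom: Optional[str] = None,
    dedup: bool = True,
) -> list[SnvRecord]:
    """Read SNVs from a VCF file, assigning every record to ``sample_id``.

    VCF POS is 1-based; records are stored at ``pos0 = POS - 1``.
    Multi-allelic sites yield one record per single-base ALT. Indels and
    symbolic alleles are skipped; the skipped count is logged.
    """
    from cyvcf2 import VCF

    if not sample_id:
        raise ValueError("sample_id must be non-empty")
    if not os.path.exists(path):
        raise GenomicIOError(f"VCF not found: {path}")

    records: list[SnvRecord] = []
    n_skipped = 0
    try:
        vcf = VCF(str(path))
        for var in vcf:
            ref = var.REF
            for alt in var.ALT:
                if len(ref) == 1 and len(alt) == 1 and ref != alt \
                        and ref in "ACGTN" and alt in "ACGTN":
                    records.append(
                        SnvRecord(
                            chrom=_normalize_chrom(var.CHROM, normalize_chrom),
                            pos0=var.POS - 1,
                            sample_id=sample_id,
                            ref=ref,
                            alt=alt,
                        )
                    )
                else:
                    n_skipped += 1
        vcf.close()
    except OSError as exc:
        raise GenomicIOError(f"cannot read VCF {path}: {exc}") from exc
    if n_skipped:
        logger.info("vcf=%s non_snv_alleles_skipped=%d", path, n_skipped)
    if dedup:
        records, _ = dedupe_snvs(records)
    return records


def read_regions_bed(
    path: PathLike, *, normalize_chrom: Optional[str] = None
) -> list[Region]:
    """Read a BED3+ region catalogue; annotation is left unset.

    Input order is preserved. Lines with ``start >= end`` raise an error
    naming the line.
    """
    regions: list[Region] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise GenomicIOError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError as exc:
            raise GenomicIOError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise GenomicIOError(
                f"{path}:{lineno}: start {start} is not below end {end}"
            )
        regions.append(Region(_normalize_chrom(fields[0], normalize_chrom), start, end))
    if not regions:
        logger.warning("regions=%s empty_catalogue=1", path)
    return regions


def read_promoters_bed(
    path: PathLike,
    gene_column: int = 4,
    *,
    normalize_chrom: Optional[str] = None,
) -> list[Region]:
    """Read a promoter catalogue (BED with a gene-symbol column).

    ``gene_column`` is 1-based; multiple genes may be comma-joined in one
    field. Each line becomes a promoter Region.
    """
    promoters: list[Region] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < max(3, gene_column):
            raise GenomicIOError(
                f"{path}:{lineno}: expected >= {max(3, gene_column)} columns"
            )
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError as exc:
            raise GenomicIOError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise GenomicIOError(f"{path}:{lineno}: start {start} is not below end {end}")
        genes = tuple(g for g in fields[gene_column - 1].split(",") if g)
        if not genes:
            raise GenomicIOError(f"{path}:{lineno}: empty gene name")
        promoters.append(
            Region(
                _normalize_chrom(fields[0], normalize_chrom),
                start,
                end,
                annotation=PROMOTER,
                gene_names=genes,
            )
        )
    return promoters


def read_snp_catalogue(
    path: PathLike,
    maf_column: int = 4,
    *,
    normalize_chrom: Optional[str] = None,
) -> list[SnpCatalogueEntry]:
    """Read a dbSNP-style BED catalogue of known polymorphisms.

    ``maf_column`` (1-based) holds the minor allele frequency; a missing
    column, empty field or ``.`` means MAF unknown. Multi-bp lines contribute
    one entry per covered position.
    """
    entries: list[SnpCatalogueEntry] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise GenomicIOError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError as exc:
            raise GenomicIOError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise GenomicIOError(f"{path}:{lineno}: start {start} is not below end {end}")
        maf: Optional[float] = None
        if maf_column - 1 < len(fields):
            raw = fields[maf_column - 1]
            if raw not in ("", "."):
                try:
                    maf = float(raw)
                except ValueError as exc:
                    raise GenomicIOError(f"{path}:{lineno}: bad MAF {raw!r}") from exc
                if math.isnan(maf):
                    maf = None
        chrom = _normalize_chrom(fields[0], normalize_chrom)
        for pos in range(start, end):
            entries.append(SnpCatalogueEntry(chrom, pos, maf))
    return entries


def derive_promoter_catalogue(
    gtf_path: PathLike,
    upstream: int = 2000,
    downstream: int = 500,
    *,
    normalize_chrom: Optional[str] = None,
) -> list[Region]:
    """Build promoter windows around transcript TSSs from a Gencode-style GTF.

    For a transcript whose TSS is at 1-based position *t*, the window is
    ``[t-1-upstream, t-1+downstream+1)`` on the plus strand and
    ``[t-1-downstream, t-1+upstream+1)`` on the minus strand (0-based
    half-open), clipped at 0. Overlapping or touching windows of the same
    gene are merged; distinct genes keep separate entries even if their
    windows overlap.
    """
    import gffutils

    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[tuple[str, str], list[tuple[int, int]]] = {}
    n_tx = 0
    for tx in db.features_of_type("transcript"):
        n_tx += 1
        if tx.strand not in ("+", "-"):
            raise GenomicIOError(
                f"transcript {tx.id} lacks a usable strand ({tx.strand!r})"
            )
        names = tx.attributes.get("gene_name")
        if not names:
            raise GenomicIOError(f"transcript {tx.id} lacks a gene_name attribute")
        gene = names[0]
        if tx.strand == "+":
            t = tx.start  # 1-based TSS
            start0 = max(0, t - 1 - upstream)
            end0 = t - 1 + downstream + 1
        else:
            t = tx.end
            start0 = max(0, t - 1 - downstream)
            end0 = t - 1 + upstream + 1
        chrom = _normalize_chrom(tx.seqid, normalize_chrom)
        per_gene.setdefault((chrom, gene), []).append((start0, end0))
    if n_tx == 0:
        raise GenomicIOError(f"no transcript records found in {gtf_path}")

    promoters: list[Region] = []
    for (chrom, gene), ivals in per_gene.items():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e:  # overlap or book-ended: one promoter for the gene
                cur_e = max(cur_e, e)
            else:
                promoters.append(
                    Region(chrom, cur_s, cur_e, annotation=PROMOTER, gene_names=(gene,))
                )
                cur_s, cur_e = s, e
        promoters.append(
            Region(chrom, cur_s, cur_e, annotation=PROMOTER, gene_names=(gene,))
        )
    promoters.sort(key=lambda r: (r.chrom, r.start0, r.end0, r.gene_names))
    return promoters


def _sorted_results(results: Iterable[EnrichmentResult]) -> list[EnrichmentResult]:
    return sorted(results, key=lambda r: (r.region.chrom, r.region.start0, r.region.end0))


def format_results_table(results: Iterable[EnrichmentResult]) -> str:
    """Render the full per-region results table as TSV text."""
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in _sorted_results(results):
        reg = r.region
        lines.append(
            "\t".join(
                [
                    reg.chrom,
                    str(reg.start0),
                    str(reg.end0),
                    reg.region_id,
                    reg.annotation or "",
                    ",".join(reg.gene_names),
                    str(r.summary.n_mutations),
                    str(r.summary.n_unique_samples),
                    repr(r.summary.region_rate),
                    repr(r.background_rate) if r.background_rate is not None else "",
                    repr(r.p_value),
                    repr(r.q_value),
                    str(r.passes_rate_threshold),
                    str(r.significant),
                    str(r.tested),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_outputs(results: Sequence[EnrichmentResult], out_dir: PathLike) -> dict[str, Path]:
    """Write the result files for a completed run.

    Produces, sorted by (chrom, start0) and deterministic given equal input:

    * ``results.tsv`` — every tested and untested region with statistics;
    * ``significant_promoter_genes.txt`` — unique gene symbols whose promoter
      regions are significant (for gene-ontology analyses);
    * ``significant_distal.bed`` — BED of significant distal elements (for
      target-gene association tools);
    * ``scatter_data.tsv`` — per significant region, the number of unique
      mutated samples and -log10(q), with the promoter/distal class column.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise GenomicIOError(f"output directory {out} is not writable: {exc}") from exc

    ordered = _sorted_results(results)
    paths = {
        "results": out / "results.tsv",
        "promoter_genes": out / "significant_promoter_genes.txt",
        "distal_bed": out / "significant_distal.bed",
        "scatter": out / "scatter_data.tsv",
    }

    paths["results"].write_text(format_results_table(ordered))

    genes = sorted(
        {
            g
            for r in ordered
            if r.significant and r.region.annotation == PROMOTER
            for g in r.region.gene_names
        }
    )
    paths["promoter_genes"].write_text("".join(g + "\n" for g in genes))

    distal_lines = [
        f"{r.region.chrom}\t{r.region.start0}\t{r.region.end0}\t{r.region.region_id}\n"
        for r in ordered
        if r.significant and r.region.annotation == DISTAL
    ]
    paths["distal_bed"].write_text("".join(distal_lines))

    from .pipeline import scatter_data  # deferred: pipeline imports this module

    paths["scatter"].write_text(scatter_data(ordered).to_csv(sep="\t", index=False))
    return paths
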