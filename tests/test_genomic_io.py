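"""Readers, the GTF promoter derivation, and output writing."""

import textwrap

import pytest

from smurf import (
    DISTAL,
    PROMOTER,
    EnrichmentResult,
    Region,
    RegionMutationSummary,
    SnvRecord,
    derive_promoter_catalogue,
    read_regions_bed,
    read_snp_catalogue,
    read_snvs_bed,
    read_snvs_vcf,
    write_outputs,
)
from smurf.genomic_io import GenomicIOError, dedupe_snvs


class TestReadSnvsBed:
    def test_single_base_line_maps_directly(self, bed_writer):
        path = bed_writer("s.bed", [("chr1", 100, 101, "S1")])
        (rec,) = read_snvs_bed(path, sample_column=4)
        assert (rec.chrom, rec.pos0, rec.sample_id) == ("chr1", 100, "S1")

    def test_multi_base_interval_rejected_as_non_snv(self, bed_writer):
        path = bed_writer("s.bed", [("chr1", 100, 105, "S1")])
        with pytest.raises(GenomicIOError, match="single-nucleotide"):
            read_snvs_bed(path, sample_column=4)

    def test_sample_from_filename(self, bed_writer):
        path = bed_writer(
            "patient7.bed", [("chr1", 1, 2), ("chr1", 5, 6), ("chr2", 9, 10)]
        )
        recs = read_snvs_bed(path, sample_column="from-filename")
        assert [r.sample_id for r in recs] == ["patient7"] * 3

    def test_missing_sample_column_errors_with_line_number(self, bed_writer):
        path = bed_writer("s.bed", [("chr1", 1, 2, "S1"), ("chr1", 5, 6)])
        with pytest.raises(GenomicIOError, match=":2"):
            read_snvs_bed(path, sample_column=4)

    def test_malformed_coordinates_name_the_line(self, bed_writer):
        path = bed_writer("s.bed", [("chr1", "x", 2, "S1")])
        with pytest.raises(GenomicIOError, match=":1"):
            read_snvs_bed(path, sample_column=4)

    def test_duplicate_calls_deduplicated_on_read(self, bed_writer):
        path = bed_writer("s.bed", [("chr1", 7, 8, "S1")] * 3 + [("chr1", 7, 8, "S2")])
        recs = read_snvs_bed(path, sample_column=4)
        assert len(recs) == 2  # one per (position, sample)


class TestReadSnvsVcf:
    HEADER = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=100000>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
        """
    )

    def _write(self, tmp_path, body):
        path = tmp_path / "cohort.vcf"
        path.write_text(self.HEADER + body)
        return path

    def test_one_based_position_converted(self, tmp_path):
        path = self._write(tmp_path, "chr1\t1000\t.\tA\tG\t.\t.\t.\n")
        (rec,) = read_snvs_vcf(path, "S1")
        assert (rec.pos0, rec.ref, rec.alt) == (999, "A", "G")

    def test_indel_skipped(self, tmp_path):
        path = self._write(
            tmp_path, "chr1\t10\t.\tA\tAT\t.\t.\t.\nchr1\t20\t.\tC\tT\t.\t.\t.\n"
        )
        recs = read_snvs_vcf(path, "S1")
        assert [r.pos0 for r in recs] == [19]

    def test_multiallelic_site_splits_per_alt(self, tmp_path):
        path = self._write(tmp_path, "chr1\t50\t.\tC\tG,T\t.\t.\t.\n")
        recs = read_snvs_vcf(path, "S1")
        assert len(recs) == 2
        assert {r.alt for r in recs} == {"G", "T"}
        assert {r.pos0 for r in recs} == {49}

    def test_unreadable_vcf_errors(self, tmp_path):
        with pytest.raises(GenomicIOError):
            read_snvs_vcf(tmp_path / "nope.vcf", "S1")

    def test_empty_sample_id_rejected(self, tmp_path):
        path = self._write(tmp_path, "")
        with pytest.raises(ValueError, match="sample_id"):
            read_snvs_vcf(path, "")


class TestReadRegionsBed:
    def test_basic_read_preserves_order(self, bed_writer):
        path = bed_writer("r.bed", [("chr2", 500, 900), ("chr1", 0, 10)])
        regions = read_regions_bed(path)
        assert [(r.chrom, r.start0, r.end0) for r in regions] == [
            ("chr2", 500, 900),
            ("chr1", 0, 10),
        ]
        assert regions[0].length == 400
        assert regions[0].annotation is None

    def test_inverted_interval_errors_with_line(self, bed_writer):
        path = bed_writer("r.bed", [("chr2", 900, 500)])
        with pytest.raises(GenomicIOError, match=":1"):
            read_regions_bed(path)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("")
        assert read_regions_bed(path) == []


class TestSnpCatalogue:
    def test_maf_parsed_and_missing_allowed(self, bed_writer):
        path = bed_writer(
            "snp.bed",
            [("chr1", 10, 11, "0.05"), ("chr1", 20, 21, "."), ("chr1", 30, 31)],
        )
        entries = read_snp_catalogue(path)
        assert [(e.pos0, e.maf) for e in entries] == [(10, 0.05), (20, None), (30, None)]

    def test_multibase_line_expands_per_position(self, bed_writer):
        path = bed_writer("snp.bed", [("chr1", 5, 8, "0.2")])
        assert [e.pos0 for e in read_snp_catalogue(path)] == [5, 6, 7]


GTF_LINE = (
    "{chrom}\tHAVANA\ttranscript\t{start}\t{end}\t.\t{strand}\t.\t"
    'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{name}";\n'
)


class TestDerivePromoterCatalogue:
    def test_plus_strand_window_clipped_at_zero(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            GTF_LINE.format(
                chrom="chr1", start=1000, end=2000, strand="+", gid="g1", tid="t1", name="A"
            )
        )
        (p,) = derive_promoter_catalogue(gtf, upstream=2000, downstream=500)
        assert (p.start0, p.end0) == (0, 1500)
        assert p.annotation == PROMOTER and p.gene_names == ("A",)

    def test_minus_strand_window(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            GTF_LINE.format(
                chrom="chr1", start=4000, end=5000, strand="-", gid="g1", tid="t1", name="A"
            )
        )
        (p,) = derive_promoter_catalogue(gtf, upstream=2000, downstream=500)
        assert (p.start0, p.end0) == (4499, 7000)

    def test_same_gene_nearby_tss_merged_once(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            GTF_LINE.format(
                chrom="chr1", start=10000, end=12000, strand="+", gid="g1", tid="t1", name="A"
            )
            + GTF_LINE.format(
                chrom="chr1", start=10100, end=12000, strand="+", gid="g1", tid="t2", name="A"
            )
        )
        (p,) = derive_promoter_catalogue(gtf, upstream=2000, downstream=500)
        assert (p.start0, p.end0) == (7999, 10600)
        assert p.gene_names == ("A",)

    def test_no_same_gene_overlaps_in_output(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        lines = [
            GTF_LINE.format(
                chrom="chr1",
                start=10000 + 300 * i,
                end=20000,
                strand="+",
                gid="g1",
                tid=f"t{i}",
                name="A",
            )
            for i in range(10)
        ]
        lines.append(
            GTF_LINE.format(
                chrom="chr1", start=10500, end=20000, strand="+", gid="g2", tid="tb", name="B"
            )
        )
        gtf.write_text("".join(lines))
        proms = derive_promoter_catalogue(gtf, upstream=2000, downstream=500)
        by_gene = {}
        for p in proms:
            by_gene.setdefault(p.gene_names, []).append(p)
        for gene, ps in by_gene.items():
            ps = sorted(ps, key=lambda r: r.start0)
            for a, b in zip(ps, ps[1:]):
                assert a.end0 <= b.start0, f"overlapping promoters for {gene}"

    def test_missing_gene_name_errors(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tX\ttranscript\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(GenomicIOError, match="gene_name"):
            derive_promoter_catalogue(gtf)


def _result(region, n_mut=0, samples=(), q=1.0, significant=False, tested=False):
    summ = RegionMutationSummary(region, n_mut, frozenset(samples))
    return EnrichmentResult(
        region=region,
        summary=summ,
        background_rate=1e-6 if tested else None,
        n_trials=1000 if tested else None,
        p_value=min(q, 1.0),
        q_value=q,
        passes_rate_threshold=significant,
        significant=significant,
        tested=tested,
    )


class TestWriteOutputs:
    def test_empty_significant_set_still_writes_all_files(self, tmp_path, tiny_regions):
        results = [_result(Region(r.chrom, r.start0, r.end0, DISTAL)) for r in tiny_regions]
        paths = write_outputs(results, tmp_path / "out")
        assert paths["promoter_genes"].read_text() == ""
        assert paths["distal_bed"].read_text() == ""
        table = paths["results"].read_text().splitlines()
        assert len(table) == 1 + len(tiny_regions)

    def test_gene_list_unique_and_sorted(self, tmp_path):
        r1 = Region("chr1", 0, 10, PROMOTER, ("TERT",))
        r2 = Region("chr1", 20, 30, PROMOTER, ("TERT", "TP53"))
        results = [
            _result(r1, 2, {"S1"}, q=0.01, significant=True, tested=True),
            _result(r2, 3, {"S1", "S2"}, q=0.02, significant=True, tested=True),
        ]
        paths = write_outputs(results, tmp_path / "out")
        assert paths["promoter_genes"].read_text().splitlines() == ["TERT", "TP53"]

    def test_bed_round_trip_preserves_regions(self, tmp_path):
        regions = [
            Region("chr1", 5, 50, DISTAL),
            Region("chr1", 100, 200, DISTAL),
            Region("chr2", 0, 9, DISTAL),
        ]
        results = [_result(r, 1, {"S1"}, q=0.01, significant=True, tested=True) for r in regions]
        paths = write_outputs(results, tmp_path / "out")
        back = read_regions_bed(paths["distal_bed"])
        assert [(r.chrom, r.start0, r.end0) for r in back] == [
            (r.chrom, r.start0, r.end0) for r in regions
        ]

    def test_outputs_sorted_and_deterministic(self, tmp_path):
        regions = [Region("chr2", 0, 9, DISTAL), Region("chr1", 100, 200, DISTAL)]
        results = [_result(r, 1, {"S1"}, q=0.03, significant=True, tested=True) for r in regions]
        p1 = write_outputs(results, tmp_path / "a")
        p2 = write_outputs(list(reversed(results)), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
        first_data_line = p1["results"].read_text().splitlines()[1]
        assert first_data_line.startswith("chr1\t")


def test_vcf_bed_position_round_trip(tmp_path, bed_writer):
    """VCF -> record -> BED -> record keeps every genomic position."""
    vcf = tmp_path / "s.vcf"
    vcf.write_text(
        TestReadSnvsVcf.HEADER
        + "".join(f"chr1\t{pos}\t.\tA\tG\t.\t.\t.\n" for pos in (1, 77, 4242))
    )
    from_vcf = read_snvs_vcf(vcf, "S1")
    bed = bed_writer("S1.bed", [(r.chrom, r.pos0, r.pos0 + 1) for r in from_vcf])
    from_bed = read_snvs_bed(bed, sample_column="from-filename")
    assert [r.pos0 for r in from_bed] == [0, 76, 4241]
    assert [r.pos0 for r in from_vcf] == [r.pos0 for r in from_bed]


def test_dedupe_reports_removed_count():
    recs = [SnvRecord("chr1", 5, "S1")] * 4 + [SnvRecord("chr1", 6, "S1")]
    kept, n = dedupe_snvs(recs)
    assert len(kept) == 2 and n == 3
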