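"""Derive promoter windows from a GTF, annotate regions, filter known SNPs.

Writes a three-transcript GTF, builds TSS windows (2 kb upstream / 500 bp
downstream), classifies a small region catalogue as promoter or distal, and
shows how the known-SNP filter treats common vs rare polymorphisms.
"""

import tempfile
from pathlib import Path

from smurf import (
    Region,
    SnpCatalogueEntry,
    SnvRecord,
    annotate_regions,
    derive_promoter_catalogue,
    filter_known_snps,
)

GTF = """\
chr1\tHAVANA\ttranscript\t12000\t15000\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; gene_name "TERT";
chr1\tHAVANA\ttranscript\t12150\t15000\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; gene_name "TERT";
chr1\tHAVANA\ttranscript\t40000\t44000\t.\t-\t.\tgene_id "g2"; transcript_id "t3"; gene_name "TP53";
"""

with tempfile.TemporaryDirectory() as tmp:
    gtf = Path(tmp) / "genes.gtf"
    gtf.write_text(GTF)
    promoters = derive_promoter_catalogue(gtf, upstream=2000, downstream=500)

print("promoter windows (0-based half-open):")
for p in promoters:
    print(f"  {p.region_id}  {','.join(p.gene_names)}")
# The two TERT transcripts start 150 bp apart, so their windows merge into
# one promoter; the minus-strand TP53 window extends upstream of its TSS at
# the transcript END coordinate.

regions = [Region("chr1", 11500, 11800), Region("chr1", 30000, 30400)]
annotated = annotate_regions(regions, promoters)
for r in annotated:
    print(f"region {r.region_id}: {r.annotation} {r.gene_names or ''}")

snvs = [SnvRecord("chr1", 11600, "patient1"), SnvRecord("chr1", 11700, "patient1")]
catalogue = [
    SnpCatalogueEntry("chr1", 11600, maf=0.22),   # common polymorphism
    SnpCatalogueEntry("chr1", 11700, maf=0.004),  # rare: possibly somatic
]
kept, removed = filter_known_snps(snvs, catalogue, mode="maf")
print(f"SNP filter (maf mode): kept {len(kept)}, removed {removed}")
# Only the variant at the common-SNP position is removed; the match with
# MAF <= 1% is retained as a potentially interesting acquired variant.
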