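"""Core domain types.

All genomic coordinates are 0-based half-open (BED convention). VCF positions
are converted on read. A region's identifier is ``chrom:start0-end0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PROMOTER = "promoter"
DISTAL = "distal"

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnvRecord:
    """One somatic single-nucleotide variant with sample identity.

    ``ref``/``alt`` may be None for BED-derived records, which carry no allele
    information. When both are present they must be single, distinct bases —
    that is what makes the record an SNV rather than an indel or MNV.
    """

    chrom: str
    pos0: int
    sample_id: str
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError(f"SNV position must be >= 0, got {self.pos0}")
        if not self.sample_id:
            raise ValueError("SNV record requires a non-empty sample_id")
        if self.ref is not None and self.alt is not None:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError(
                    f"not an SNV: ref={self.ref!r} alt={self.alt!r} "
                    "(alleles must be single bases)"
                )
            if self.ref == self.alt:
                raise ValueError(f"ref and alt are identical ({self.ref!r})")


@dataclass(frozen=True)
class Region:
    """A genomic interval, optionally annotated as promoter or distal element.

    ``annotation`` is None for freshly read regions; annotation is assigned by
    :func:`smurf.snv_processing.annotate_regions`. A promoter region carries
    the gene symbols of every promoter window it overlaps.
    """

    chrom: str
    start0: int
    end0: int
    annotation: Optional[str] = None
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start0 < 0:
            raise ValueError(f"region start must be >= 0, got {self.start0}")
        if self.start0 >= self.end0:
            raise ValueError(
                f"empty or inverted region {self.chrom}:{self.start0}-{self.end0}"
            )
        if self.annotation is not None:
            if self.annotation not in (PROMOTER, DISTAL):
                raise ValueError(f"unknown annotation {self.annotation!r}")
            if self.annotation == PROMOTER and not self.gene_names:
                raise ValueError("promoter region requires gene names")
            if self.annotation == DISTAL and self.gene_names:
                raise ValueError("distal region must not carry gene names")

    @property
    def length(self) -> int:
        return self.end0 - self.start0

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start0}-{self.end0}"

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start0 <= pos0 < self.end0


@dataclass(frozen=True)
class SnpCatalogueEntry:
    """A known germline polymorphism at a single position.

    ``maf`` is the population minor allele frequency; None when the catalogue
    does not report one.
    """

    chrom: str
    pos0: int
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError(f"SNP position must be >= 0, got {self.pos0}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"MAF must be in [0, 1], got {self.maf}")


@dataclass(frozen=True)
class RegionMutationSummary:
    """Per-region mutation tally across the cohort."""

    region: Region
    n_mutations: int
    sample_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_mutations < 0:
            raise ValueError("negative mutation count")
        if len(self.sample_ids) > self.n_mutations:
            raise ValueError("more mutated samples than mutations")

    @property
    def n_unique_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def region_rate(self) -> float:
        """Mutations per base pair of the region, summed over samples."""
        return self.n_mutations / self.region.length


@dataclass(frozen=True)
class SampleRateTable:
    """Per-sample mutation rate inside the merged region catalogue.

    ``rates[s]`` is (SNVs of sample *s* inside regions) / (total region bp),
    i.e. mutations per base pair per sample. Every cohort sample appears,
    including samples with zero in-region mutations (rate 0).
    """

    rates: dict[str, float]
    total_region_bp: int

    def __post_init__(self) -> None:
        if self.total_region_bp < 1:
            raise ValueError("total_region_bp must be >= 1")
        if not self.rates:
            raise ValueError("rate table must cover at least one sample")
        for s, r in self.rates.items():
            if r < 0:
                raise ValueError(f"negative rate for sample {s}")

    @property
    def n_samples(self) -> int:
        return len(self.rates)

    def mean_rate(self) -> float:
        return sum(self.rates.values()) / len(self.rates)

    def subset_mean(self, sample_ids) -> float:
        ids = list(sample_ids)
        if not ids:
            raise ValueError("subset mean over an empty sample set")
        missing = [s for s in ids if s not in self.rates]
        if missing:
            raise KeyError(f"samples not in rate table: {missing}")
        return sum(self.rates[s] for s in ids) / len(ids)


@dataclass(frozen=True)
class ThresholdResult:
    """Inflection-point cutoff on the ranked per-region mutation rates."""

    threshold_rate: float
    rank_at_inflection: int  # 1-based rank into the ascending-sorted rates


@dataclass
class EnrichmentResult:
    """Outcome of the binomial enrichment test for one region.

    ``tested`` is False for regions with zero mutations: they are excluded
    from the test and the FDR family, and reported with p = q = 1.
    """

    region: Region
    summary: RegionMutationSummary
    background_rate: Optional[float]
    n_trials: Optional[int]
    p_value: float = 1.0
    q_value: float = 1.0
    passes_rate_threshold: bool = False
    significant: bool = False
    tested: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")
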