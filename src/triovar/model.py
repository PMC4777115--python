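"""Core domain types for trio-based variant filtering.

Coordinates are 1-based inclusive throughout, matching VCF and GTF.
All records are biallelic: multiallelic VCF rows are split on input
(see :func:`triovar.io.read_vcf`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


class GenotypeState(Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class Genotype:
    """Unphased diploid genotype as a pair of allele indices.

    ``0`` is the reference allele, ``1`` the (single) alternate allele and
    ``None`` a missing allele.  The genotype state is symmetric in allele
    order: ``0/1`` and ``1/0`` are both heterozygous.
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    phased: bool = False

    def state(self) -> GenotypeState:
        if self.allele_a is None or self.allele_b is None:
            return GenotypeState.MISSING
        if self.allele_a == self.allele_b:
            return GenotypeState.HOM_ALT if self.allele_a == 1 else GenotypeState.HOM_REF
        return GenotypeState.HET

    @classmethod
    def missing(cls) -> "Genotype":
        return cls(None, None)

    def is_missing(self) -> bool:
        return self.state() is GenotypeState.MISSING


@dataclass(frozen=True)
class SiteMetrics:
    """Site-level quality annotations as emitted by GATK-style callers.

    ``mq``
        Root-mean-square mapping quality over reads at the site.
    ``qd``
        Variant confidence normalised by depth of variant-supporting reads.
    ``fs``
        Phred-scaled Fisher exact test for strand bias (non-negative).
    ``read_pos_rank_sum``
        Rank-sum Z-score for variant position within reads; callers only
        emit it at sites with heterozygous calls, so absence is common and
        is distinct from a value of 0.
    """

    mq: Optional[float] = None
    qd: Optional[float] = None
    fs: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fs is not None and self.fs < 0:
            raise ValueError(f"FS must be non-negative, got {self.fs}")


class VariantClass(Enum):
    SNV = "SNV"
    INDEL = "INDEL"


@dataclass
class VariantRecord:
    """One biallelic variant site with per-sample genotypes."""

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str
    metrics: SiteMetrics = field(default_factory=SiteMetrics)
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    filter_status: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= VALID_BASES:
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} contains non-ACGT characters"
                )

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNV
        return VariantClass.INDEL

    @property
    def is_snv(self) -> bool:
        return self.variant_class is VariantClass.SNV

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the site for known-variant matching: exact allele match."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def genotype(self, sample_id: str) -> Genotype:
        try:
            return self.genotypes[sample_id]
        except KeyError:
            raise ConfigurationError(
                f"sample {sample_id!r} absent from record {self.chrom}:{self.pos}"
            ) from None


@dataclass(frozen=True)
class TrioSpec:
    """Pedigree roles bound to VCF sample identifiers.

    Under the autosomal recessive model the affected offspring is homozygous
    for the causal allele and both healthy parents are obligate carriers.
    """

    sire_id: str
    dam_id: str
    offspring_id: str
    offspring_affected: bool = True

    def __post_init__(self) -> None:
        ids = {self.sire_id, self.dam_id, self.offspring_id}
        if len(ids) != 3:
            raise ValueError("trio requires three distinct sample identifiers")

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.sire_id, self.dam_id, self.offspring_id)


@dataclass
class TranscriptModel:
    """A coding transcript as an ordered set of genomic CDS intervals.

    ``cds_intervals`` are 1-based inclusive ``(start, end)`` pairs sorted by
    genomic position and non-overlapping.  For a minus-strand transcript the
    coding sequence runs from the genomically last CDS base downward, reverse
    complemented.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping CDS intervals in transcript {self.transcript_id}"
                )
        self.cds_intervals = ivs
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.transcript_id} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """Map a genomic position to its 1-based coding-nucleotide position.

        Returns ``None`` for positions outside every CDS interval.
        """
        offset = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if s <= pos <= e:
                    return offset + (pos - s) + 1
                offset += e - s + 1
        else:
            for s, e in reversed(self.cds_intervals):
                if s <= pos <= e:
                    return offset + (e - pos) + 1
                offset += e - s + 1
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= self.cds_length:
            raise ValueError(f"cds_pos {cds_pos} outside CDS of {self.transcript_id}")
        remaining = cds_pos
        if self.strand == "+":
            for s, e in self.cds_intervals:
                width = e - s + 1
                if remaining <= width:
                    return s + remaining - 1
                remaining -= width
        else:
            for s, e in reversed(self.cds_intervals):
                width = e - s + 1
                if remaining <= width:
                    return e - remaining + 1
                remaining -= width
        raise AssertionError("unreachable")

    def contains(self, pos: int) -> bool:
        return self.genomic_to_cds(pos) is not None

    def coding_sequence(self, reference: dict[str, str]) -> str:
        """Spliced coding sequence in translation order."""
        seq = "".join(
            reference[self.chrom][s - 1 : e] for s, e in self.cds_intervals
        )
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq.upper()


class Phenotype(Enum):
    UNAFFECTED = 1
    AFFECTED = 2
    UNKNOWN = 0


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    sample_id: str
    sire_id: str  # "0" for founder
    dam_id: str
    sex: int
    phenotype: Phenotype


@dataclass
class Pedigree:
    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        ids = {r.sample_id for r in self.records}
        for r in self.records:
            for parent in (r.sire_id, r.dam_id):
                if parent not in ("0", "-9") and parent not in ids:
                    raise ValueError(
                        f"parent {parent!r} of {r.sample_id} not present in pedigree"
                    )

    def __iter__(self):
        return iter(self.records)


class TriovarError(Exception):
    """Base class for errors raised by this package."""


class VcfParseError(TriovarError):
    pass


class ConfigurationError(TriovarError):
    pass


class DataIntegrityError(TriovarError):
    pass
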