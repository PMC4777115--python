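"""Functional classification of variants against transcript models.

Coding SNVs partition into exactly one of MISSENSE / NONSENSE / SILENT by
translating the affected codon before and after substitution with the
standard genetic code; coding indels are FRAMESHIFT_INDEL when the length
change is not a multiple of 3, else INFRAME_INDEL.  Everything else —
intergenic, intronic, UTR, splice region — is NONCODING, matching the
coarse exonic/non-exonic triage a trio filtering funnel needs.

Classification yields HGVS-style names such as ``c.155G>C`` and ``p.R52P``:
coding position 155 lies in codon ceil(155/3) = 52 at within-codon
position 2, and an arginine codon CGA with G→C at that position becomes
proline CCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from intervaltree import IntervalTree

from .model import (
    DataIntegrityError,
    TranscriptModel,
    VariantRecord,
    complement,
)

#: Standard genetic code (NCBI translation table 1), stop = '*'.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class Category(Enum):
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    SILENT = "silent"
    NONCODING = "noncoding"


#: Higher = more severe; used to pick the per-record summary consequence.
SEVERITY: dict[Category, int] = {
    Category.FRAMESHIFT_INDEL: 5,
    Category.NONSENSE: 4,
    Category.MISSENSE: 3,
    Category.INFRAME_INDEL: 2,
    Category.SILENT: 1,
    Category.NONCODING: 0,
}


@dataclass(frozen=True)
class Consequence:
    category: Category
    transcript_id: Optional[str] = None
    gene_id: Optional[str] = None
    cds_pos: Optional[int] = None
    codon_index: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    cdna_name: Optional[str] = None
    protein_name: Optional[str] = None
    flags: tuple[str, ...] = ()

    @property
    def severity(self) -> int:
        return SEVERITY[self.category]


NONCODING = Consequence(category=Category.NONCODING)


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in CODON_TABLE:
        raise DataIntegrityError(f"codon {codon!r} contains non-ACGT bases")
    return CODON_TABLE[codon]


def codon_index_of(cds_pos: int) -> int:
    """1-based codon index: codon_index = ceil(cds_pos / 3)."""
    return (cds_pos + 2) // 3


def position_in_codon(cds_pos: int) -> int:
    """1-based position within the codon: ((cds_pos - 1) mod 3) + 1."""
    return (cds_pos - 1) % 3 + 1


def locate_in_cds(
    record: VariantRecord,
    transcript: TranscriptModel,
    reference: Optional[dict[str, str]] = None,
) -> Optional[int]:
    """Coding-nucleotide position of an SNV, or ``None`` if non-coding.

    Counting starts at 1 on the first coding base; for a minus-strand
    transcript it runs from the genomically last CDS base downward.  When a
    reference is supplied the record's REF allele is checked against it.
    """
    if transcript.chrom != record.chrom:
        return None
    if reference is not None and record.is_snv:
        ref_base = reference[record.chrom][record.pos - 1].upper()
        if ref_base != record.ref:
            raise DataIntegrityError(
                f"REF allele {record.ref} at {record.chrom}:{record.pos} does not "
                f"match reference base {ref_base}"
            )
    return transcript.genomic_to_cds(record.pos)


def classify_snv(
    record: VariantRecord,
    transcript: TranscriptModel,
    reference: dict[str, str],
    _cds: Optional[str] = None,
) -> Consequence:
    """Classify a coding SNV by translating the affected codon.

    For minus-strand transcripts the genomic alleles are complemented into
    coding-strand alleles before substitution.  Initiator-codon loss and
    stop-codon loss are reported as MISSENSE with an explanatory flag (the
    latter with alt_aa = 'X', a readthrough marker), preserving the
    three-way missense/nonsense/silent partition of coding SNVs.
    """
    cds_pos = locate_in_cds(record, transcript, reference)
    if cds_pos is None:
        raise ValueError(
            f"{record.chrom}:{record.pos} is not in the CDS of {transcript.transcript_id}"
        )
    cds = _cds if _cds is not None else transcript.coding_sequence(reference)
    if transcript.strand == "+":
        cdna_ref, cdna_alt = record.ref, record.alt
    else:
        cdna_ref, cdna_alt = complement(record.ref), complement(record.alt)
    if cds[cds_pos - 1] != cdna_ref:
        raise DataIntegrityError(
            f"coding base {cds[cds_pos - 1]} at c.{cds_pos} of "
            f"{transcript.transcript_id} does not match REF allele {cdna_ref}"
        )
    codon_idx = codon_index_of(cds_pos)
    pos_in_codon = position_in_codon(cds_pos)
    ref_codon = cds[(codon_idx - 1) * 3 : codon_idx * 3]
    alt_codon = (
        ref_codon[: pos_in_codon - 1] + cdna_alt + ref_codon[pos_in_codon:]
    )
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)

    flags: tuple[str, ...] = ()
    if ref_aa == alt_aa:
        category = Category.SILENT
    elif alt_aa == "*":
        category = Category.NONSENSE
    elif ref_aa == "*":
        category = Category.MISSENSE
        alt_aa = "X"  # stop-loss readthrough marker
        flags = ("stop_loss",)
    else:
        category = Category.MISSENSE
        if codon_idx == 1 and ref_codon == "ATG":
            flags = ("start_loss",)

    return Consequence(
        category=category,
        transcript_id=transcript.transcript_id,
        gene_id=transcript.gene_id,
        cds_pos=cds_pos,
        codon_index=codon_idx,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        cdna_name=f"c.{cds_pos}{cdna_ref}>{cdna_alt}",
        protein_name=f"p.{ref_aa}{codon_idx}{alt_aa}",
        flags=flags,
    )


def indel_overlaps_cds(record: VariantRecord, transcript: TranscriptModel) -> bool:
    """Whether an indel touches the CDS.

    A deletion overlaps when any anchored/deleted reference base
    (pos .. pos + len(ref) - 1) lies in a CDS interval; a pure insertion
    uses the base immediately after the anchor.
    """
    if transcript.chrom != record.chrom:
        return False
    if len(record.ref) > 1:
        positions = range(record.pos, record.pos + len(record.ref))
    else:
        positions = (record.pos + 1,)
    return any(transcript.contains(p) for p in positions)


def classify_indel(record: VariantRecord, transcript: TranscriptModel) -> Consequence:
    """FRAMESHIFT_INDEL iff |len(alt) - len(ref)| mod 3 != 0."""
    delta = abs(len(record.alt) - len(record.ref))
    category = (
        Category.FRAMESHIFT_INDEL if delta % 3 != 0 else Category.INFRAME_INDEL
    )
    return Consequence(
        category=category,
        transcript_id=transcript.transcript_id,
        gene_id=transcript.gene_id,
    )


@dataclass
class AnnotatedVariant:
    record: VariantRecord
    consequences: list[Consequence] = field(default_factory=list)

    @property
    def summary(self) -> Consequence:
        """Most severe consequence across overlapping transcripts."""
        if not self.consequences:
            return NONCODING
        return max(self.consequences, key=lambda c: c.severity)


def build_transcript_index(
    transcripts: list[TranscriptModel],
) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over transcript CDS spans."""
    index: dict[str, IntervalTree] = {}
    for tx in transcripts:
        start, end = tx.span
        # IntervalTree is half-open; +1 makes the 1-based inclusive end queryable
        index.setdefault(tx.chrom, IntervalTree()).addi(start, end + 1, tx)
    return index


def annotate_all(
    records: list[VariantRecord],
    transcripts: list[TranscriptModel],
    reference: dict[str, str],
) -> dict[tuple[str, int, str, str], AnnotatedVariant]:
    """Annotate every record against every overlapping transcript.

    Returns a map keyed by (chrom, pos, ref, alt); each entry carries all
    per-transcript consequences plus a most-severe summary.
    """
    index = build_transcript_index(transcripts)
    cds_cache = {tx.transcript_id: tx.coding_sequence(reference) for tx in transcripts}
    annotated: dict[tuple[str, int, str, str], AnnotatedVariant] = {}
    for record in records:
        consequences: list[Consequence] = []
        tree = index.get(record.chrom)
        if tree is None:
            hits = ()
        elif record.is_snv:
            hits = tree[record.pos]
        else:
            # deletions span pos..pos+len(ref)-1; insertions anchor at pos+1
            hits = tree.overlap(record.pos, record.pos + len(record.ref) + 1)
        for hit in hits:
            tx: TranscriptModel = hit.data
            if record.is_snv:
                if tx.contains(record.pos):
                    consequences.append(
                        classify_snv(
                            record, tx, reference, _cds=cds_cache[tx.transcript_id]
                        )
                    )
                else:
                    consequences.append(
                        Consequence(
                            category=Category.NONCODING,
                            transcript_id=tx.transcript_id,
                            gene_id=tx.gene_id,
                        )
                    )
            else:
                if indel_overlaps_cds(record, tx):
                    consequences.append(classify_indel(record, tx))
                else:
                    consequences.append(
                        Consequence(
                            category=Category.NONCODING,
                            transcript_id=tx.transcript_id,
                            gene_id=tx.gene_id,
                        )
                    )
        annotated[record.key] = AnnotatedVariant(record=record, consequences=consequences)
    return annotated
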