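"""Consequence classifier vs an independent translate-and-diff oracle."""

import random

import pytest
from Bio.Seq import Seq

from triovar.consequence import (
    CODON_TABLE,
    Category,
    annotate_all,
    classify_indel,
    classify_snv,
    codon_index_of,
    locate_in_cds,
    position_in_codon,
)
from triovar.model import (
    DataIntegrityError,
    TranscriptModel,
    VariantRecord,
    complement,
)


def test_codon_table_matches_published_standard_code():
    for codon, aa in CODON_TABLE.items():
        assert aa == str(Seq(codon).translate()), codon
    assert len(CODON_TABLE) == 64


# A plus-strand transcript whose codon 52 is CGA (Arg), so the 155th coding
# base is the middle G: a G>C there gives CCA (Pro), i.e. c.155G>C / p.R52P.
def _arg52_transcript():
    rng = random.Random(3)
    aa_codons = [c for c, aa in CODON_TABLE.items() if aa != "*"]
    codons = [rng.choice(aa_codons) for _ in range(60)]
    codons[0] = "ATG"
    codons[51] = "CGA"
    cds = "".join(codons)
    seq = "TTTTT" + cds + "TTTTT"
    reference = {"chrA": seq}
    tx = TranscriptModel(
        gene_id="FAM83G_like",
        transcript_id="tx1",
        chrom="chrA",
        strand="+",
        cds_intervals=[(6, 5 + len(cds))],
    )
    return reference, tx


def test_codon_arithmetic_identities():
    assert codon_index_of(155) == 52
    assert position_in_codon(155) == 2
    assert codon_index_of(1) == 1 and position_in_codon(1) == 1
    assert codon_index_of(3) == 1 and position_in_codon(3) == 3
    assert codon_index_of(4) == 2 and position_in_codon(4) == 1


def test_arg_to_pro_missense_at_codon_52():
    reference, tx = _arg52_transcript()
    record = VariantRecord(chrom="chrA", pos=5 + 155, ref="G", alt="C")
    assert locate_in_cds(record, tx, reference) == 155
    consequence = classify_snv(record, tx, reference)
    assert consequence.category is Category.MISSENSE
    assert (consequence.codon_index, consequence.cds_pos) == (52, 155)
    assert (consequence.ref_aa, consequence.alt_aa) == ("R", "P")
    assert consequence.cdna_name == "c.155G>C"
    assert consequence.protein_name == "p.R52P"


def test_stop_gain_and_silent_examples():
    reference, tx = _arg52_transcript()
    # codon 52 CGA: C>T at codon position 1 (cds 154) -> TGA stop
    record = VariantRecord(chrom="chrA", pos=5 + 154, ref="C", alt="T")
    assert classify_snv(record, tx, reference).category is Category.NONSENSE
    # CGA G>A at position 3 (cds 156) -> CGG, still Arg
    base156 = reference["chrA"][5 + 156 - 1]
    record = VariantRecord(chrom="chrA", pos=5 + 156, ref=base156, alt="G")
    assert classify_snv(record, tx, reference).category is Category.SILENT


def test_reference_mismatch_is_data_integrity_error():
    reference, tx = _arg52_transcript()
    wrong_ref = "A" if reference["chrA"][5 + 154] != "A" else "T"
    record = VariantRecord(chrom="chrA", pos=5 + 155, ref=wrong_ref, alt="C")
    with pytest.raises(DataIntegrityError):
        classify_snv(record, tx, reference)


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("G", "GT", Category.FRAMESHIFT_INDEL),  # 1-bp insertion
        ("GACT", "G", Category.INFRAME_INDEL),  # 3-bp deletion
        ("GACTG", "G", Category.FRAMESHIFT_INDEL),  # 4-bp deletion
    ],
)
def test_indel_frameshift_rule(ref, alt, expected):
    reference, tx = _arg52_transcript()
    record = VariantRecord(chrom="chrA", pos=20, ref=ref, alt=alt)
    assert classify_indel(record, tx).category is expected


def oracle_category(
    record: VariantRecord, tx: TranscriptModel, reference: dict[str, str]
) -> Category:
    """Independent oracle: translate the full mutant vs reference CDS and diff."""
    chrom_seq = reference[record.chrom]
    mutant_seq = (
        chrom_seq[: record.pos - 1] + record.alt + chrom_seq[record.pos :]
    )
    def protein(seq):
        cds = "".join(seq[s - 1 : e] for s, e in tx.cds_intervals)
        if tx.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return str(Seq(cds).translate())

    ref_protein = protein(chrom_seq)
    alt_protein = protein(mutant_seq)
    if ref_protein == alt_protein:
        return Category.SILENT
    diffs = [
        (a, b) for a, b in zip(ref_protein, alt_protein) if a != b
    ]
    assert len(diffs) == 1
    ref_aa, alt_aa = diffs[0]
    if alt_aa == "*" and ref_aa != "*":
        return Category.NONSENSE
    return Category.MISSENSE


def _random_coding_snvs(reference, transcripts, rng, n):
    variants = []
    while len(variants) < n:
        tx = rng.choice(transcripts)
        cds_pos = rng.randint(1, tx.cds_length)
        pos = tx.cds_to_genomic(cds_pos)
        ref = reference[tx.chrom][pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        variants.append((VariantRecord(chrom=tx.chrom, pos=pos, ref=ref, alt=alt), tx))
    return variants


def test_classifier_equals_translate_and_diff_oracle(small_reference):
    """Incremental codon classification agrees with whole-protein diffing
    for 1,000 random coding SNVs on both strands."""
    reference, transcripts = small_reference
    rng = random.Random(99)
    strands_seen = set()
    for record, tx in _random_coding_snvs(reference, transcripts, rng, 1000):
        strands_seen.add(tx.strand)
        got = classify_snv(record, tx, reference).category
        assert got is oracle_category(record, tx, reference), (record.key, tx.strand)
    assert strands_seen == {"+", "-"}


def test_strand_involution(small_reference):
    """Classifying on a minus-strand transcript equals classifying the
    reverse-complemented locus on the equivalent plus-strand transcript."""
    reference, transcripts = small_reference
    rng = random.Random(13)
    minus = [t for t in transcripts if t.strand == "-"]
    for record, tx in _random_coding_snvs(reference, minus, rng, 100):
        length = len(reference[tx.chrom])
        flipped_seq = str(Seq(reference[tx.chrom]).reverse_complement())
        flipped_tx = TranscriptModel(
            gene_id=tx.gene_id,
            transcript_id=tx.transcript_id,
            chrom=tx.chrom,
            strand="+",
            cds_intervals=[
                (length - e + 1, length - s + 1) for s, e in tx.cds_intervals
            ],
        )
        flipped_record = VariantRecord(
            chrom=record.chrom,
            pos=length - record.pos + 1,
            ref=complement(record.ref),
            alt=complement(record.alt),
        )
        a = classify_snv(record, tx, reference)
        b = classify_snv(flipped_record, flipped_tx, {tx.chrom: flipped_seq})
        assert a.category is b.category
        assert a.cds_pos == b.cds_pos
        assert (a.ref_aa, a.alt_aa) == (b.ref_aa, b.alt_aa)
        assert a.cdna_name == b.cdna_name


def test_annotate_all_summary_and_severity(small_reference):
    reference, transcripts = small_reference
    # a record overlapping no transcript is NONCODING
    record = VariantRecord(chrom="chr1", pos=len(reference["chr1"]) - 2, ref=reference["chr1"][-3], alt="A" if reference["chr1"][-3] != "A" else "C")
    annotated = annotate_all([record], transcripts, reference)[record.key]
    assert annotated.summary.category is Category.NONCODING


def test_summary_takes_most_severe_across_transcripts():
    # one locus, silent in tx1 (+) but missense in tx2 (-): summary missense
    # tx1 codon GCT with T>C at pos 3 -> GCC (Ala, silent on plus strand)
    seq = "AA" + "ATG" + "GCT" + "TAA" + "AA"  # positions 3..11 CDS
    reference = {"c": seq}
    tx1 = TranscriptModel("g1", "t1", "c", "+", [(3, 11)])
    # minus-strand transcript over the same span; genomic T>C at pos 8
    tx2 = TranscriptModel("g2", "t2", "c", "-", [(3, 11)])
    pos = 8
    record = VariantRecord(chrom="c", pos=pos, ref=seq[pos - 1], alt="C")
    a1 = classify_snv(record, tx1, reference)
    a2 = classify_snv(record, tx2, reference)
    assert a1.category is Category.SILENT
    assert a2.category is not Category.SILENT
    annotated = annotate_all([record], [tx1, tx2], reference)[record.key]
    assert annotated.summary.category is a2.category


def test_coding_snv_partition(small_sim, small_reference):
    """missense + nonsense + silent = coding-SNV total over any record set."""
    reference, transcripts = small_reference
    snvs = [r for r in small_sim.records if r.is_snv]
    annotations = annotate_all(snvs, transcripts, reference)
    coding = [
        a.summary.category
        for a in annotations.values()
        if a.summary.category in (Category.MISSENSE, Category.NONSENSE, Category.SILENT)
    ]
    exonic_snvs = [
        a
        for a in annotations.values()
        if a.record.is_snv and a.summary.category is not Category.NONCODING
    ]
    assert len(coding) == len(exonic_snvs)
    assert len(coding) > 0
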