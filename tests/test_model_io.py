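"""Domain types and format round-trips."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triovar.io import (
    extract_trio,
    read_ped,
    read_transcripts,
    read_vcf,
    write_fasta,
    write_gtf,
    write_vcf,
    read_fasta,
)
from triovar.model import (
    ConfigurationError,
    Genotype,
    GenotypeState,
    SiteMetrics,
    TranscriptModel,
    VariantClass,
    VariantRecord,
    reverse_complement,
)

allele_indices = st.one_of(st.none(), st.integers(min_value=0, max_value=1))


@settings(derandomize=True)
@given(a=allele_indices, b=allele_indices)
def test_genotype_state_symmetric_and_total(a, b):
    gt, swapped = Genotype(a, b), Genotype(b, a)
    assert gt.state() is swapped.state()
    if a is None or b is None:
        assert gt.state() is GenotypeState.MISSING
    else:
        assert gt.state() is not GenotypeState.MISSING


def test_variant_class_from_allele_lengths():
    snv = VariantRecord(chrom="chr1", pos=10, ref="G", alt="C")
    deletion = VariantRecord(chrom="chr1", pos=10, ref="GAT", alt="G")
    insertion = VariantRecord(chrom="chr1", pos=10, ref="G", alt="GTT")
    assert snv.variant_class is VariantClass.SNV
    assert deletion.variant_class is VariantClass.INDEL
    assert insertion.variant_class is VariantClass.INDEL


@pytest.mark.parametrize(
    "ref,alt", [("G", "G"), ("", "C"), ("G", ""), ("N", "C"), ("G", "X")]
)
def test_invalid_alleles_rejected(ref, alt):
    with pytest.raises(ValueError):
        VariantRecord(chrom="chr1", pos=1, ref=ref, alt=alt)


def test_negative_fs_rejected():
    with pytest.raises(ValueError):
        SiteMetrics(fs=-1.0)


def test_absent_metric_distinct_from_zero():
    assert SiteMetrics(fs=None).fs is None
    assert SiteMetrics(fs=0.0).fs == 0.0


# ---------------------------------------------------------------- VCF I/O

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr5>
##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsire\tdam\toffspring
"""


def _write(tmp_path, body):
    path = tmp_path / "in.vcf"
    path.write_text(VCF_HEADER + body)
    return path


def test_read_vcf_trio_row(tmp_path):
    # the FAM83G-style site: parents het, affected offspring hom-alt
    path = _write(
        tmp_path,
        "chr5\t41055619\t.\tG\tC\t.\t.\tMQ=55;QD=12\tGT\t0/1\t0/1\t1/1\n",
    )
    (rec,) = list(read_vcf(path))
    assert (rec.chrom, rec.pos, rec.ref, rec.alt) == ("chr5", 41055619, "G", "C")
    assert rec.variant_class is VariantClass.SNV
    assert rec.metrics.mq == pytest.approx(55.0)
    assert rec.metrics.qd == pytest.approx(12.0)
    assert rec.metrics.fs is None
    assert rec.genotypes["sire"].state() is GenotypeState.HET
    assert rec.genotypes["dam"].state() is GenotypeState.HET
    assert rec.genotypes["offspring"].state() is GenotypeState.HOM_ALT


def test_read_vcf_missing_and_half_calls(tmp_path):
    path = _write(
        tmp_path,
        "chr5\t100\t.\tG\tC\t.\t.\tMQ=50\tGT\t./.\t./1\t0/1\n",
    )
    (rec,) = list(read_vcf(path))
    assert rec.genotypes["sire"].state() is GenotypeState.MISSING
    assert rec.genotypes["dam"].state() is GenotypeState.MISSING
    assert rec.genotypes["offspring"].state() is GenotypeState.HET


# expected recodings of original GT pairs against alt 1 and alt 2 of a
# two-alt row, hand-computed: target alt -> 1, ref -> 0, other alt -> missing
MULTIALLELIC_TABLE = {
    (0, 0): {1: GenotypeState.HOM_REF, 2: GenotypeState.HOM_REF},
    (0, 1): {1: GenotypeState.HET, 2: GenotypeState.MISSING},
    (0, 2): {1: GenotypeState.MISSING, 2: GenotypeState.HET},
    (1, 1): {1: GenotypeState.HOM_ALT, 2: GenotypeState.MISSING},
    (1, 2): {1: GenotypeState.MISSING, 2: GenotypeState.MISSING},
    (2, 2): {1: GenotypeState.MISSING, 2: GenotypeState.HOM_ALT},
}


@pytest.mark.parametrize("gt_pair", sorted(MULTIALLELIC_TABLE))
def test_multiallelic_split_recoding(tmp_path, gt_pair):
    a, b = gt_pair
    path = _write(
        tmp_path,
        f"chr5\t100\t.\tG\tC,T\t.\t.\tMQ=50\tGT\t{a}/{b}\t0/0\t0/0\n",
    )
    records = list(read_vcf(path))
    assert [r.alt for r in records] == ["C", "T"]
    for alt_index, rec in enumerate(records, start=1):
        expected = MULTIALLELIC_TABLE[gt_pair][alt_index]
        assert rec.genotypes["sire"].state() is expected, (gt_pair, alt_index)
        # sample count conserved on split
        assert len(rec.genotypes) == 3


def test_multiallelic_split_never_invents_hom_alt(tmp_path):
    # HOM_ALT for a split allele requires both original indices equal to it
    for a in range(3):
        for b in range(a, 3):
            path = _write(
                tmp_path,
                f"chr5\t100\t.\tG\tC,T\t.\t.\tMQ=50\tGT\t{a}/{b}\t0/0\t0/0\n",
            )
            for alt_index, rec in enumerate(read_vcf(path), start=1):
                if rec.genotypes["sire"].state() is GenotypeState.HOM_ALT:
                    assert (a, b) == (alt_index, alt_index)


def test_read_vcf_sample_subset_errors(tmp_path):
    path = _write(tmp_path, "chr5\t100\t.\tG\tC\t.\t.\tMQ=50\tGT\t0/1\t0/1\t1/1\n")
    with pytest.raises(ConfigurationError):
        list(read_vcf(path, sample_subset=["nobody"]))


def test_vcf_round_trip_random_records(tmp_path, small_sim):
    """Synthetic records survive write -> read with field-level equality."""
    records = small_sim.records[:100]
    out = tmp_path / "rt.vcf"
    write_vcf(records, out)
    back = list(read_vcf(out))
    assert len(back) == len(records)
    for original, copy in zip(records, back):
        assert copy.key == original.key
        assert copy.genotypes == original.genotypes
        for name in ("mq", "qd", "fs", "read_pos_rank_sum"):
            a, b = getattr(original.metrics, name), getattr(copy.metrics, name)
            if a is None:
                assert b is None
            else:
                assert math.isclose(a, b, rel_tol=1e-6)


def test_write_vcf_empty_record_list(tmp_path):
    out = tmp_path / "empty.vcf"
    write_vcf([], out)
    assert list(read_vcf(out)) == []
    assert out.read_text().startswith("##fileformat=VCF")


# ---------------------------------------------------------------- PED

def _ped(tmp_path, rows):
    path = tmp_path / "trio.ped"
    path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
    return path


TRIO_ROWS = [
    ("F1", "sire", 0, 0, 1, 1),
    ("F1", "dam", 0, 0, 2, 1),
    ("F1", "kid", "sire", "dam", 1, 2),
]


def test_extract_trio_from_ped(tmp_path):
    trio = extract_trio(read_ped(_ped(tmp_path, TRIO_ROWS)))
    assert (trio.sire_id, trio.dam_id, trio.offspring_id) == ("sire", "dam", "kid")
    assert trio.offspring_affected


def test_extract_trio_requires_exactly_one_affected(tmp_path):
    two_affected = TRIO_ROWS + [("F1", "sib", "sire", "dam", 2, 2)]
    with pytest.raises(ConfigurationError):
        extract_trio(read_ped(_ped(tmp_path, two_affected)))
    unaffected_child = [TRIO_ROWS[0], TRIO_ROWS[1], ("F1", "kid", "sire", "dam", 1, 1)]
    with pytest.raises(ConfigurationError):
        extract_trio(read_ped(_ped(tmp_path, unaffected_child)))


# ---------------------------------------------------------------- GTF / FASTA

GTF_PLUS = (
    'chr1\tx\tCDS\t11\t70\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\tx\tCDS\t101\t160\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
)


def test_read_transcripts_two_exon_plus_strand(tmp_path):
    gtf = tmp_path / "a.gtf"
    gtf.write_text(GTF_PLUS)
    (tx,) = read_transcripts(gtf)
    assert tx.cds_length == 120
    assert tx.cds_intervals == [(11, 70), (101, 160)]
    assert (tx.gene_id, tx.transcript_id, tx.strand) == ("g1", "t1", "+")


def test_read_transcripts_skips_non_triplet_cds(tmp_path, caplog):
    gtf = tmp_path / "b.gtf"
    gtf.write_text(
        GTF_PLUS
        + 'chr1\tx\tCDS\t201\t300\t.\t+\t0\tgene_id "g2"; transcript_id "t2";\n'
    )
    transcripts = read_transcripts(gtf)
    assert [t.transcript_id for t in transcripts] == ["t1"]


def test_minus_strand_coding_sequence_matches_revcomp_oracle(tmp_path):
    rng = random.Random(11)
    seq = "".join(rng.choice("ACGT") for _ in range(400))
    reference = {"chr1": seq}
    tx = TranscriptModel(
        gene_id="g",
        transcript_id="t",
        chrom="chr1",
        strand="-",
        cds_intervals=[(21, 80), (141, 200), (261, 320)],
    )
    # independent oracle: slice, concatenate in descending order, complement
    oracle = "".join(
        "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in seq[s - 1 : e][::-1])
        for s, e in [(261, 320), (141, 200), (21, 80)]
    )
    assert tx.coding_sequence(reference) == oracle
    assert tx.coding_sequence(reference) == reverse_complement(
        seq[20:80] + seq[140:200] + seq[260:320]
    )


def test_gtf_fasta_round_trip(tmp_path, small_reference):
    reference, transcripts = small_reference
    write_fasta(reference, tmp_path / "g.fa")
    write_gtf(transcripts, tmp_path / "g.gtf")
    assert read_fasta(tmp_path / "g.fa") == reference
    back = read_transcripts(tmp_path / "g.gtf")
    original = {t.transcript_id: t for t in transcripts}
    assert len(back) == len(original)
    for tx in back:
        assert tx.cds_intervals == original[tx.transcript_id].cds_intervals
        assert tx.strand == original[tx.transcript_id].strand
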