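"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 (via pysam), 6-column PED, GTF with CDS features (via gffutils)
and FASTA (via Biopython).  All coordinates are 1-based inclusive in
memory; the 0-based conversion pysam uses internally is not exposed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gffutils
import pysam
from Bio import SeqIO

from .model import (
    ConfigurationError,
    Genotype,
    Pedigree,
    PedigreeRecord,
    Phenotype,
    SiteMetrics,
    TranscriptModel,
    TrioSpec,
    TriovarError,
    VALID_BASES,
    VariantRecord,
    VcfParseError,
)

logger = logging.getLogger(__name__)

_INFO_FIELDS = (
    ("MQ", "RMS mapping quality"),
    ("QD", "Variant confidence normalized by depth"),
    ("FS", "Phred-scaled Fisher strand bias"),
    ("ReadPosRankSum", "Rank-sum test of variant position within reads"),
)


def _metric(info, key: str) -> Optional[float]:
    value = info.get(key)
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0]
    return float(value)


def _recode_allele(allele: Optional[int], target_alt: int) -> Optional[int]:
    """Recode an original allele index for one split biallelic record.

    Reference stays 0, the target alternate becomes 1 and any *other*
    alternate becomes missing: a sample carrying a different alt allele can
    satisfy neither HET nor HOM_ALT for the target allele, and treating it
    as reference would fabricate evidence.
    """
    if allele is None:
        return None
    if allele == 0:
        return 0
    if allele == target_alt:
        return 1
    return None


def read_vcf(
    path: str | Path, sample_subset: Optional[list[str]] = None
) -> Iterator[VariantRecord]:
    """Stream biallelic :class:`VariantRecord` objects from a VCF file.

    Multiallelic rows are split into one record per alternate allele, with
    genotypes recoded per allele.  Rows whose alleles contain non-ACGT
    characters (symbolic alleles, spanning deletions) are skipped with a
    warning.  Absent INFO metrics are represented as ``None``.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc

    samples = list(vcf.header.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in samples]
        if missing:
            raise ConfigurationError(
                f"{path}: requested samples absent from VCF: {', '.join(missing)}"
            )
        samples = list(sample_subset)

    header_lines = len(str(vcf.header).rstrip("\n").split("\n"))
    row = 0
    while True:
        try:
            rec = next(vcf, None)
        except (OSError, ValueError) as exc:
            raise VcfParseError(
                f"{path}: malformed VCF row at line {header_lines + row + 1}: {exc}"
            ) from exc
        if rec is None:
            break
        row += 1
        line_no = header_lines + row
        if rec.alts is None:
            continue
        metrics = SiteMetrics(
            mq=_metric(rec.info, "MQ"),
            qd=_metric(rec.info, "QD"),
            fs=_metric(rec.info, "FS"),
            read_pos_rank_sum=_metric(rec.info, "ReadPosRankSum"),
        )
        filters = {f for f in rec.filter.keys() if f not in ("PASS", ".")}
        ref = rec.ref.upper()
        if not set(ref) <= VALID_BASES:
            logger.warning(
                "%s line %d: skipping record with non-ACGT REF %r", path, line_no, ref
            )
            continue
        for alt_index, alt in enumerate(rec.alts, start=1):
            alt = alt.upper()
            if not set(alt) <= VALID_BASES or alt == ref:
                logger.warning(
                    "%s line %d: skipping alt allele %r", path, line_no, alt
                )
                continue
            if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and (
                ref[1:2] == alt[1:2]
            ):
                logger.warning(
                    "%s line %d: ref and alt share a prefix longer than 1; "
                    "indel may not be left-aligned",
                    path,
                    line_no,
                )
            genotypes: dict[str, Genotype] = {}
            for s in samples:
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None or len(gt) != 2:
                    genotypes[s] = Genotype.missing()
                    continue
                a, b = gt
                genotypes[s] = Genotype(
                    _recode_allele(a, alt_index), _recode_allele(b, alt_index)
                )
            try:
                yield VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    metrics=metrics,
                    genotypes=genotypes,
                    filter_status=set(filters),
                )
            except ValueError as exc:
                raise VcfParseError(f"{path} line {line_no}: {exc}") from exc
    vcf.close()


def _build_header(
    samples: list[str], contigs: list[str], filters: Iterable[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    for key, desc in _INFO_FIELDS:
        header.info.add(key, 1, "Float", desc)
    header.formats.add("GT", 1, "String", "Genotype")
    for label in sorted(filters):
        header.filters.add(label, None, None, f"Failed hard filter {label}")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write biallelic records as an uncompressed VCF 4.2 file.

    Round-trips through :func:`read_vcf` preserving chrom, pos, alleles,
    genotypes and site metrics (metrics to float32 precision, the VCF
    storage type).
    """
    records = list(records)
    samples: list[str] = []
    contigs: list[str] = []
    filters: set[str] = set()
    for rec in records:
        for s in rec.genotypes:
            if s not in samples:
                samples.append(s)
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
        filters |= rec.filter_status
    header = _build_header(samples, contigs, filters)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            row = out.new_record(
                contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            metric_items = (
                ("MQ", rec.metrics.mq),
                ("QD", rec.metrics.qd),
                ("FS", rec.metrics.fs),
                ("ReadPosRankSum", rec.metrics.read_pos_rank_sum),
            )
            for key, value in metric_items:
                if value is not None:
                    row.info[key] = value
            if rec.filter_status:
                for label in sorted(rec.filter_status):
                    row.filter.add(label)
            else:
                row.filter.add("PASS")
            for s in samples:
                gt = rec.genotypes.get(s, Genotype.missing())
                row.samples[s]["GT"] = (gt.allele_a, gt.allele_b)
                row.samples[s].phased = False
            out.write(row)


_PHENOTYPE_CODES = {
    "1": Phenotype.UNAFFECTED,
    "2": Phenotype.AFFECTED,
    "0": Phenotype.UNKNOWN,
    "-9": Phenotype.UNKNOWN,
}


def read_ped(path: str | Path) -> Pedigree:
    """Read a whitespace-delimited 6-column PED file.

    Phenotype coding: 1 = unaffected, 2 = affected, 0 or -9 = unknown.
    """
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise TriovarError(
                    f"{path} line {line_no}: expected 6 columns, got {len(fields)}"
                )
            fam, sample, sire, dam, sex, pheno = fields[:6]
            if pheno not in _PHENOTYPE_CODES:
                raise TriovarError(
                    f"{path} line {line_no}: unknown phenotype code {pheno!r}"
                )
            records.append(
                PedigreeRecord(
                    family_id=fam,
                    sample_id=sample,
                    sire_id=sire,
                    dam_id=dam,
                    sex=int(sex),
                    phenotype=_PHENOTYPE_CODES[pheno],
                )
            )
    return Pedigree(records)


def extract_trio(pedigree: Pedigree) -> TrioSpec:
    """Extract the unique affected-offspring trio from a pedigree.

    Requires exactly one affected individual with both parents present in
    the pedigree; zero or more than one raises an error demanding explicit
    selection.
    """
    founders = ("0", "-9")
    trios = [
        r
        for r in pedigree
        if r.phenotype is Phenotype.AFFECTED
        and r.sire_id not in founders
        and r.dam_id not in founders
    ]
    if len(trios) != 1:
        raise ConfigurationError(
            f"pedigree contains {len(trios)} affected offspring with both parents "
            "present; exactly one is required (select the trio explicitly)"
        )
    offspring = trios[0]
    return TrioSpec(
        sire_id=offspring.sire_id,
        dam_id=offspring.dam_id,
        offspring_id=offspring.sample_id,
        offspring_affected=True,
    )


def read_transcripts(gtf_path: str | Path) -> list[TranscriptModel]:
    """Build transcript models from the CDS features of a GTF file.

    CDS phase is ignored; the reading frame is derived from the order of
    the intervals.  Transcripts whose total CDS length is not divisible by
    3 are skipped with a warning.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feature in db.features_of_type("CDS"):
        tid = feature.attributes["transcript_id"][0]
        entry = grouped.setdefault(
            tid,
            {
                "gene_id": feature.attributes.get("gene_id", ["?"])[0],
                "chrom": feature.seqid,
                "strand": feature.strand,
                "intervals": [],
            },
        )
        entry["intervals"].append((feature.start, feature.end))
    transcripts = []
    for tid, entry in grouped.items():
        try:
            transcripts.append(
                TranscriptModel(
                    gene_id=entry["gene_id"],
                    transcript_id=tid,
                    chrom=entry["chrom"],
                    strand=entry["strand"],
                    cds_intervals=entry["intervals"],
                )
            )
        except ValueError as exc:
            logger.warning("skipping transcript %s: %s", tid, exc)
    return transcripts


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a chrom -> uppercase sequence map."""
    return {
        record.id: str(record.seq).upper() for record in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(reference: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF CDS features with correct frame attributes."""
    with open(path, "w") as fh:
        for tx in transcripts:
            intervals = (
                tx.cds_intervals
                if tx.strand == "+"
                else list(reversed(tx.cds_intervals))
            )
            coding_offset = 0
            rows = []
            for start, end in intervals:
                frame = (3 - coding_offset % 3) % 3
                rows.append((start, end, frame))
                coding_offset += end - start + 1
            for start, end, frame in sorted(rows):
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{tx.chrom}\ttriovar\tCDS\t{start}\t{end}\t.\t{tx.strand}\t{frame}\t{attrs}\n"
                )
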