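"""Synthetic inputs with the statistical structure the trio analysis assumes.

The generator emulates the study design end to end: a random reference
genome with coding transcripts on both strands, a biallelic trio VCF with
Mendelian-consistent genotypes and GATK-style site metrics, exactly one
planted recessive causal missense variant that survives every filter, and
decoy variants engineered to die at each elimination stage (hard filter,
non-exonic, wrong inheritance pattern, known, non-deleterious or silent,
manual inspection).  A truth table records each variant's designed
elimination stage, giving an end-to-end oracle for the pipeline.

Genotype draws use the integer RNG and metrics are rounded, so output is
byte-identical across platforms under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio.Seq import Seq

from .model import (
    Genotype,
    SiteMetrics,
    TranscriptModel,
    TrioSpec,
    TriovarError,
    VariantRecord,
    complement,
)
from .filters import FilterThresholds
from .io import write_fasta, write_gtf, write_vcf

BASES = "ACGT"

#: Designed elimination stages, in pipeline order.
STAGE_HARD_FILTER = "hard_filter"
STAGE_EXONIC = "exonic"
STAGE_CONDITIONAL = "conditional"
STAGE_NOVEL = "novel"
STAGE_DELETERIOUS = "deleterious"
STAGE_INSPECTION = "inspection"
STAGE_PASSED = "passed"


@dataclass
class SimulationConfig:
    seed: int = 1
    # genome shape
    n_chroms: int = 5
    chrom_length: int = 100_000
    n_genes: int = 50
    exons_per_gene: int = 3
    cds_exon_length: int = 100
    intron_length: int = 150
    # variant load
    n_decoy_variants: int = 5_000
    fraction_known: float = 0.30
    fraction_coding: float = 0.20
    fraction_metric_fail: float = 0.10
    fraction_indel: float = 0.15
    # site-metric distributions (truncated normals)
    mq_mean: float = 55.0
    mq_sd: float = 5.0
    qd_mean: float = 20.0
    qd_sd: float = 6.0
    fs_mean: float = 3.0
    fs_sd: float = 3.0
    rprs_mean: float = 0.0
    rprs_sd: float = 1.5
    # cohort
    n_cases: int = 8
    n_controls: int = 16
    carrier_rate: float = 0.20
    n_cohort_decoys: int = 3
    # trio sample ids
    sire_id: str = "sire"
    dam_id: str = "dam"
    offspring_id: str = "offspring"

    def __post_init__(self) -> None:
        for name in (
            "fraction_known",
            "fraction_coding",
            "fraction_metric_fail",
            "fraction_indel",
            "carrier_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise TriovarError(f"{name} must lie in [0, 1], got {value}")
        if (self.exons_per_gene * self.cds_exon_length) % 3 != 0:
            raise TriovarError("total CDS length per gene must be divisible by 3")
        span = self.gene_span + 2 * self.intron_length
        per_chrom = -(-self.n_genes // self.n_chroms)
        if per_chrom * span > self.chrom_length:
            raise TriovarError(
                f"chrom_length {self.chrom_length} cannot accommodate "
                f"{per_chrom} genes of span {span}"
            )

    @property
    def gene_span(self) -> int:
        return (
            self.exons_per_gene * self.cds_exon_length
            + (self.exons_per_gene - 1) * self.intron_length
        )

    @property
    def trio(self) -> TrioSpec:
        return TrioSpec(
            sire_id=self.sire_id,
            dam_id=self.dam_id,
            offspring_id=self.offspring_id,
        )


def simulate_reference(
    config: SimulationConfig, rng: Optional[random.Random] = None
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Random genome plus non-overlapping coding transcripts on both strands."""
    rng = rng if rng is not None else random.Random(config.seed)
    reference = {
        f"chr{i + 1}": "".join(
            rng.choice(BASES) for _ in range(config.chrom_length)
        )
        for i in range(config.n_chroms)
    }
    chroms = list(reference)
    transcripts: list[TranscriptModel] = []
    per_chrom = -(-config.n_genes // config.n_chroms)
    slot = config.chrom_length // per_chrom
    gene_no = 0
    for chrom_idx, chrom in enumerate(chroms):
        for slot_idx in range(per_chrom):
            if gene_no >= config.n_genes:
                break
            gene_no += 1
            margin = slot - config.gene_span
            start = slot_idx * slot + 1 + rng.randrange(max(margin - 10, 1))
            intervals = []
            pos = start
            for _ in range(config.exons_per_gene):
                intervals.append((pos, pos + config.cds_exon_length - 1))
                pos += config.cds_exon_length + config.intron_length
            strand = rng.choice("+-")
            transcripts.append(
                TranscriptModel(
                    gene_id=f"gene_{gene_no:04d}",
                    transcript_id=f"tx_{gene_no:04d}",
                    chrom=chrom,
                    strand=strand,
                    cds_intervals=intervals,
                )
            )
    return reference, transcripts


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _aa_change(
    cds: str, cds_pos: int, coding_alt: str
) -> tuple[str, str]:
    codon_idx = (cds_pos + 2) // 3
    offset = (cds_pos - 1) % 3
    ref_codon = cds[(codon_idx - 1) * 3 : codon_idx * 3]
    alt_codon = ref_codon[:offset] + coding_alt + ref_codon[offset + 1 :]
    return _translate(ref_codon), _translate(alt_codon)


@dataclass
class SimulatedTrio:
    """Everything simulate_trio_vcf produces, in memory."""

    records: list[VariantRecord]
    pedigree_rows: list[tuple[str, str, str, str, int, int]]
    known_records: list[VariantRecord]
    scores: dict[tuple[str, int, str, str], float]
    inspection: dict[tuple[str, int, str, str], bool]
    truth: dict[tuple[str, int, str, str], str]  # key -> designed stage
    planted_key: tuple[str, int, str, str]
    trio: TrioSpec


class _PositionBroker:
    """Hands out unused genomic positions, coding and non-coding."""

    def __init__(
        self,
        reference: dict[str, str],
        transcripts: list[TranscriptModel],
        rng: random.Random,
    ) -> None:
        self.reference = reference
        self.rng = rng
        self.used: dict[str, set[int]] = {c: set() for c in reference}
        self.cds_positions: dict[str, set[int]] = {c: set() for c in reference}
        coding_pool: list[tuple[TranscriptModel, int]] = []
        for tx in transcripts:
            for s, e in tx.cds_intervals:
                for pos in range(s, e + 1):
                    self.cds_positions[tx.chrom].add(pos)
                    coding_pool.append((tx, pos))
        rng.shuffle(coding_pool)
        self._coding_pool = coding_pool

    def take_coding(self) -> tuple[TranscriptModel, int]:
        while self._coding_pool:
            tx, pos = self._coding_pool.pop()
            if pos not in self.used[tx.chrom]:
                self.used[tx.chrom].add(pos)
                return tx, pos
        raise TriovarError(
            "simulation demands more coding variants than there is CDS space"
        )

    def take_noncoding(self, span: int = 1) -> tuple[str, int]:
        chroms = sorted(self.reference)
        for _ in range(100_000):
            chrom = self.rng.choice(chroms)
            pos = self.rng.randrange(1, len(self.reference[chrom]) - span)
            footprint = range(pos, pos + span)
            if any(p in self.cds_positions[chrom] for p in footprint):
                continue
            if any(p in self.used[chrom] for p in footprint):
                continue
            self.used[chrom].update(footprint)
            return chrom, pos
        raise TriovarError("could not place a non-coding variant; genome too dense")


def _round2(x: float) -> float:
    return round(x, 2)


def _passing_metrics(
    config: SimulationConfig,
    rng: random.Random,
    is_snv: bool,
    any_het: bool,
    thresholds: FilterThresholds,
) -> SiteMetrics:
    fs_max = thresholds.fs_max_snv if is_snv else thresholds.fs_max_indel
    rprs_min = thresholds.rprs_min_snv if is_snv else thresholds.rprs_min_indel
    mq = max(_round2(rng.gauss(config.mq_mean, config.mq_sd)), thresholds.mq_min)
    qd = max(_round2(rng.gauss(config.qd_mean, config.qd_sd)), thresholds.qd_min)
    fs = min(max(_round2(rng.gauss(config.fs_mean, config.fs_sd)), 0.0), fs_max)
    rprs = (
        max(_round2(rng.gauss(config.rprs_mean, config.rprs_sd)), rprs_min)
        if any_het
        else None
    )
    return SiteMetrics(mq=mq, qd=qd, fs=fs, read_pos_rank_sum=rprs)


def _failing_metrics(
    config: SimulationConfig,
    rng: random.Random,
    is_snv: bool,
    any_het: bool,
    thresholds: FilterThresholds,
) -> SiteMetrics:
    base = _passing_metrics(config, rng, is_snv, any_het, thresholds)
    choices = ["mq", "qd", "fs"] + (["rprs"] if any_het else [])
    victim = rng.choice(choices)
    mq, qd, fs, rprs = base.mq, base.qd, base.fs, base.read_pos_rank_sum
    if victim == "mq":
        mq = _round2(rng.uniform(10.0, thresholds.mq_min - 0.1))
    elif victim == "qd":
        qd = _round2(rng.uniform(0.0, thresholds.qd_min - 0.1))
    elif victim == "fs":
        fs_max = thresholds.fs_max_snv if is_snv else thresholds.fs_max_indel
        fs = _round2(rng.uniform(fs_max + 0.1, fs_max * 2))
    else:
        rprs_min = thresholds.rprs_min_snv if is_snv else thresholds.rprs_min_indel
        rprs = _round2(rng.uniform(rprs_min * 2, rprs_min - 0.1))
    return SiteMetrics(mq=mq, qd=qd, fs=fs, read_pos_rank_sum=rprs)


_GT_POOL = [(0, 0), (0, 1), (1, 1)]


def _mendelian_genotypes(rng: random.Random) -> tuple[Genotype, Genotype, Genotype]:
    sire = rng.choice(_GT_POOL)
    dam = rng.choice(_GT_POOL)
    child = tuple(sorted((rng.choice(sire), rng.choice(dam))))
    return Genotype(*sire), Genotype(*dam), Genotype(*child)


def _pattern_genotypes() -> tuple[Genotype, Genotype, Genotype]:
    return Genotype(0, 1), Genotype(0, 1), Genotype(1, 1)


def _non_pattern_genotypes(rng: random.Random) -> tuple[Genotype, Genotype, Genotype]:
    while True:
        sire, dam, child = _mendelian_genotypes(rng)
        if not (
            sire.allele_a != sire.allele_b
            and dam.allele_a != dam.allele_b
            and child == Genotype(1, 1)
        ):
            return sire, dam, child


def _random_alt(ref_base: str, rng: random.Random) -> str:
    return rng.choice([b for b in BASES if b != ref_base])


def _coding_substitution(
    tx: TranscriptModel,
    pos: int,
    cds: str,
    reference: dict[str, str],
    rng: random.Random,
    want: str,
) -> Optional[str]:
    """Pick a genomic alt base producing the wanted class, or None.

    ``want`` is ``silent``, ``missense`` or ``any``.  Amino-acid effects
    are computed by whole-codon translation (Biopython), independently of
    the pipeline's own classifier.
    """
    cds_pos = tx.genomic_to_cds(pos)
    assert cds_pos is not None
    genomic_ref = reference[tx.chrom][pos - 1]
    coding_ref = genomic_ref if tx.strand == "+" else complement(genomic_ref)
    candidates = [b for b in BASES if b != coding_ref]
    rng.shuffle(candidates)
    for coding_alt in candidates:
        ref_aa, alt_aa = _aa_change(cds, cds_pos, coding_alt)
        if want == "silent" and ref_aa != alt_aa:
            continue
        if want == "missense" and not (
            ref_aa != alt_aa and ref_aa != "*" and alt_aa != "*"
        ):
            continue
        return coding_alt if tx.strand == "+" else complement(coding_alt)
    return None


def _coding_decoy_weights(config: SimulationConfig) -> list[tuple[str, float]]:
    rest = 1.0 - config.fraction_known
    return [
        ("known", config.fraction_known),
        ("inheritance", rest * 0.50),
        ("silent", rest * 0.20),
        ("missense_nondel", rest * 0.15),
        ("missense_noscore", rest * 0.05),
        ("missense_inspect", rest * 0.10),
    ]


def simulate_trio_vcf(
    config: SimulationConfig,
    reference: dict[str, str],
    transcripts: list[TranscriptModel],
    rng: Optional[random.Random] = None,
    thresholds: Optional[FilterThresholds] = None,
) -> SimulatedTrio:
    """Trio VCF with one planted causal variant among engineered decoys."""
    rng = rng if rng is not None else random.Random(config.seed + 1)
    thresholds = thresholds or FilterThresholds()
    broker = _PositionBroker(reference, transcripts, rng)
    trio = config.trio
    s_id, d_id, o_id = trio.sire_id, trio.dam_id, trio.offspring_id
    cds_cache = {
        tx.transcript_id: tx.coding_sequence(reference) for tx in transcripts
    }

    records: list[VariantRecord] = []
    known_records: list[VariantRecord] = []
    scores: dict[tuple[str, int, str, str], float] = {}
    inspection: dict[tuple[str, int, str, str], bool] = {}
    truth: dict[tuple[str, int, str, str], str] = {}

    def add_record(
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        genotypes: tuple[Genotype, Genotype, Genotype],
        stage: str,
        fail_metrics: bool = False,
    ) -> VariantRecord:
        sire, dam, child = genotypes
        any_het = any(
            g.allele_a is not None and g.allele_a != g.allele_b
            for g in (sire, dam, child)
        )
        is_snv = len(ref) == 1 and len(alt) == 1
        metric_fn = _failing_metrics if fail_metrics else _passing_metrics
        record = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            metrics=metric_fn(config, rng, is_snv, any_het, thresholds),
            genotypes={s_id: sire, d_id: dam, o_id: child},
        )
        records.append(record)
        truth[record.key] = stage
        return record

    # ---- planted causal missense variant: survives every stage ----
    while True:
        tx, pos = broker.take_coding()
        alt = _coding_substitution(
            tx, pos, cds_cache[tx.transcript_id], reference, rng, "missense"
        )
        if alt is not None:
            break
    planted = add_record(
        tx.chrom,
        pos,
        reference[tx.chrom][pos - 1],
        alt,
        _pattern_genotypes(),
        STAGE_PASSED,
    )
    scores[planted.key] = 0.01
    inspection[planted.key] = True

    # ---- decoys ----
    coding_weights = _coding_decoy_weights(config)
    for _ in range(config.n_decoy_variants):
        u = rng.random()
        if u < config.fraction_metric_fail:
            category = "hard_filter"
        elif rng.random() >= config.fraction_coding:
            category = "noncoding"
        else:
            v = rng.random()
            acc = 0.0
            category = coding_weights[-1][0]
            for name, w in coding_weights:
                acc += w
                if v < acc:
                    category = name
                    break

        if category in ("hard_filter", "noncoding"):
            make_indel = rng.random() < config.fraction_indel
            if make_indel and rng.random() < 0.5:
                # deletion
                span = rng.randint(2, 4)
                chrom, pos = broker.take_noncoding(span=span)
                ref = reference[chrom][pos - 1 : pos - 1 + span]
                alt = ref[0]
            elif make_indel:
                # insertion
                chrom, pos = broker.take_noncoding()
                ref = reference[chrom][pos - 1]
                alt = ref + "".join(
                    rng.choice(BASES) for _ in range(rng.randint(1, 3))
                )
            else:
                chrom, pos = broker.take_noncoding()
                ref = reference[chrom][pos - 1]
                alt = _random_alt(ref, rng)
            genotypes = _mendelian_genotypes(rng)
            add_record(
                chrom,
                pos,
                ref,
                alt,
                genotypes,
                STAGE_HARD_FILTER if category == "hard_filter" else STAGE_EXONIC,
                fail_metrics=category == "hard_filter",
            )
            continue

        # coding decoys
        if category == "inheritance":
            tx, pos = broker.take_coding()
            ref = reference[tx.chrom][pos - 1]
            alt = _random_alt(ref, rng)
            add_record(
                tx.chrom, pos, ref, alt, _non_pattern_genotypes(rng), STAGE_CONDITIONAL
            )
        elif category == "known":
            tx, pos = broker.take_coding()
            ref = reference[tx.chrom][pos - 1]
            alt = _random_alt(ref, rng)
            record = add_record(
                tx.chrom, pos, ref, alt, _pattern_genotypes(), STAGE_NOVEL
            )
            known_records.append(
                VariantRecord(chrom=record.chrom, pos=record.pos, ref=ref, alt=alt)
            )
        elif category == "silent":
            while True:
                tx, pos = broker.take_coding()
                alt = _coding_substitution(
                    tx, pos, cds_cache[tx.transcript_id], reference, rng, "silent"
                )
                if alt is not None:
                    break
            add_record(
                tx.chrom,
                pos,
                reference[tx.chrom][pos - 1],
                alt,
                _pattern_genotypes(),
                STAGE_DELETERIOUS,
            )
        else:  # missense_* categories
            while True:
                tx, pos = broker.take_coding()
                alt = _coding_substitution(
                    tx, pos, cds_cache[tx.transcript_id], reference, rng, "missense"
                )
                if alt is not None:
                    break
            if category == "missense_nondel":
                record = add_record(
                    tx.chrom,
                    pos,
                    reference[tx.chrom][pos - 1],
                    alt,
                    _pattern_genotypes(),
                    STAGE_DELETERIOUS,
                )
                scores[record.key] = round(rng.uniform(0.05, 0.95), 3)
            elif category == "missense_noscore":
                add_record(
                    tx.chrom,
                    pos,
                    reference[tx.chrom][pos - 1],
                    alt,
                    _pattern_genotypes(),
                    STAGE_DELETERIOUS,
                )
            else:  # missense_inspect: deleterious but refuted by inspection
                record = add_record(
                    tx.chrom,
                    pos,
                    reference[tx.chrom][pos - 1],
                    alt,
                    _pattern_genotypes(),
                    STAGE_INSPECTION,
                )
                scores[record.key] = round(rng.uniform(0.0, 0.049), 3)
                inspection[record.key] = False

    # extra known sites never simulated in the trio, plus same-position
    # different-alt entries, to exercise the allele-exact matching rule
    for _ in range(20):
        chrom, pos = broker.take_noncoding()
        ref = reference[chrom][pos - 1]
        known_records.append(
            VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=_random_alt(ref, rng))
        )
    novel_coding = [r for r in records if truth[r.key] == STAGE_DELETERIOUS][:5]
    for r in novel_coding:
        other_alts = [b for b in BASES if b not in (r.ref, r.alt)]
        known_records.append(
            VariantRecord(chrom=r.chrom, pos=r.pos, ref=r.ref, alt=rng.choice(other_alts))
        )

    chrom_order = {c: i for i, c in enumerate(sorted(reference))}
    records.sort(key=lambda r: (chrom_order[r.chrom], r.pos, r.alt))
    known_records.sort(key=lambda r: (chrom_order[r.chrom], r.pos, r.alt))

    pedigree_rows = [
        ("FAM1", s_id, "0", "0", 1, 1),
        ("FAM1", d_id, "0", "0", 2, 1),
        ("FAM1", o_id, s_id, d_id, 1, 2),
    ]
    return SimulatedTrio(
        records=records,
        pedigree_rows=pedigree_rows,
        known_records=known_records,
        scores=scores,
        inspection=inspection,
        truth=truth,
        planted_key=planted.key,
        trio=trio,
    )


def simulate_cohort(
    config: SimulationConfig,
    causal: VariantRecord,
    decoys: list[VariantRecord],
    rng: Optional[random.Random] = None,
) -> tuple[list[str], list[tuple[str, str, dict[str, str]]]]:
    """Case/control genotype matrix: causal column concordant, decoys not.

    Returns (variant columns, rows of (sample, phenotype, column -> genotype
    string)).  All cases are hom-alt at the causal variant; controls carry
    it heterozygously at ``carrier_rate`` and are hom-ref otherwise.  Every
    decoy column gets at least one concordance-breaking genotype.
    """
    if config.n_cases < 1:
        raise TriovarError("cohort requires at least one case")
    rng = rng if rng is not None else random.Random(config.seed + 2)
    variants = [causal] + list(decoys[: config.n_cohort_decoys])
    columns = [f"{v.chrom}:{v.pos}" for v in variants]
    case_ids = [f"case{i + 1}" for i in range(config.n_cases)]
    control_ids = [f"control{i + 1}" for i in range(config.n_controls)]

    def gt(v: VariantRecord, n_alt: int) -> str:
        return "/".join([v.alt] * n_alt + [v.ref] * (2 - n_alt))

    rows: list[tuple[str, str, dict[str, str]]] = []
    breaker: dict[str, tuple[str, int]] = {}
    for v, col in zip(variants[1:], columns[1:]):
        if rng.random() < 0.5:
            breaker[col] = (rng.choice(case_ids), rng.choice([0, 1]))
        else:
            breaker[col] = (rng.choice(control_ids), 2)
    for sample in case_ids:
        genotypes = {}
        for v, col in zip(variants, columns):
            if col in breaker and breaker[col][0] == sample:
                genotypes[col] = gt(v, breaker[col][1])
            else:
                genotypes[col] = gt(v, 2)
        rows.append((sample, "case", genotypes))
    for sample in control_ids:
        genotypes = {}
        for v, col in zip(variants, columns):
            if col in breaker and breaker[col][0] == sample:
                genotypes[col] = gt(v, breaker[col][1])
            else:
                n_alt = 1 if rng.random() < config.carrier_rate else 0
                genotypes[col] = gt(v, n_alt)
        rows.append((sample, "control", genotypes))
    return columns, rows


def write_fixture_dir(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture set for one simulation.

    Emits genome.fa, genes.gtf, trio.vcf, trio.ped, known.vcf, scores.tsv,
    inspection.tsv, cohort.tsv, cohort_variants.tsv and truth.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)
    reference, transcripts = simulate_reference(config, rng)
    sim = simulate_trio_vcf(config, reference, transcripts, rng)

    paths = {name: outdir / fname for name, fname in [
        ("fasta", "genome.fa"),
        ("gtf", "genes.gtf"),
        ("vcf", "trio.vcf"),
        ("ped", "trio.ped"),
        ("known", "known.vcf"),
        ("scores", "scores.tsv"),
        ("inspection", "inspection.tsv"),
        ("cohort", "cohort.tsv"),
        ("cohort_variants", "cohort_variants.tsv"),
        ("truth", "truth.tsv"),
    ]}
    write_fasta(reference, paths["fasta"])
    write_gtf(transcripts, paths["gtf"])
    write_vcf(sim.records, paths["vcf"])
    write_vcf(sim.known_records, paths["known"])
    with open(paths["ped"], "w") as fh:
        for row in sim.pedigree_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["scores"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tscore\n")
        for (chrom, pos, ref, alt), score in sorted(sim.scores.items()):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{score}\n")
    with open(paths["inspection"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tverdict\n")
        for (chrom, pos, ref, alt), ok in sorted(sim.inspection.items()):
            verdict = "pass" if ok else "fail"
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{verdict}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\trole\tdesigned_stage\n")
        for record in sim.records:
            chrom, pos, ref, alt = record.key
            role = "planted" if record.key == sim.planted_key else "decoy"
            fh.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{role}\t{sim.truth[record.key]}\n"
            )

    planted = next(r for r in sim.records if r.key == sim.planted_key)
    inspect_decoys = [
        r for r in sim.records
        if sim.truth[r.key] == STAGE_INSPECTION and r.is_snv
    ]
    columns, rows = simulate_cohort(config, planted, inspect_decoys)
    cohort_variants = [planted] + inspect_decoys[: config.n_cohort_decoys]
    with open(paths["cohort_variants"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\n")
        for v in cohort_variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t.\n")
    with open(paths["cohort"], "w") as fh:
        fh.write("sample\tphenotype\t" + "\t".join(columns) + "\n")
        for sample, phenotype, genotypes in rows:
            fh.write(
                f"{sample}\t{phenotype}\t"
                + "\t".join(genotypes[c] for c in columns)
                + "\n"
            )
    return paths
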