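"""End-to-end orchestration of the trio filtering funnel.

Stage order: called -> hard-filter pass -> exonic -> conditional
(recessive trio) -> novel (known subtracted) -> deleterious -> inspection
[-> cohort-concordant].  Per-stage survivor sets are retained so each
variant's observed elimination stage can be compared with a truth table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .concordance import (
    CohortTable,
    read_cohort_tsv,
    read_variants_tsv,
    recessive_concordance,
)
from .consequence import AnnotatedVariant, Category, annotate_all
from .filters import FilterThresholds, apply_hard_filters
from .funnel import FunnelReport, build_funnel
from .io import extract_trio, read_fasta, read_ped, read_transcripts, read_vcf
from .model import TrioSpec, VariantRecord
from .segregation import (
    CandidateVariant,
    VariantKey,
    deleterious_filter,
    inspection_filter,
    read_inspection_tsv,
    read_known_sites,
    read_scores_tsv,
    recessive_trio_filter,
    subtract_known,
    DELETERIOUS_THRESHOLD,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    vcf: Path
    ped: Path
    gtf: Path
    fasta: Path
    known_vcf: Optional[Path] = None
    scores: Optional[Path] = None
    inspection: Optional[Path] = None
    cohort: Optional[Path] = None
    cohort_variants: Optional[Path] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    deleterious_threshold: float = DELETERIOUS_THRESHOLD


@dataclass
class PipelineResult:
    candidates: list[CandidateVariant]
    funnel: FunnelReport
    stage_keys: dict[str, set[VariantKey]]
    annotations: dict[VariantKey, AnnotatedVariant]
    trio: TrioSpec
    concordance: Optional[dict[VariantKey, object]] = None

    def observed_elimination(self, key: VariantKey) -> str:
        """First funnel stage at which a variant disappeared, or 'passed'."""
        for stage in self.funnel.stages:
            if stage.name == "called":
                continue
            if key not in self.stage_keys[stage.name]:
                return stage.name
        return "passed"


def _breakdown(
    records: list[VariantRecord],
    annotations: dict[VariantKey, AnnotatedVariant],
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        category = annotations[r.key].summary.category.value
        counts[category] = counts.get(category, 0) + 1
    return counts


def run_pipeline(inputs: PipelineInputs) -> PipelineResult:
    reference = read_fasta(inputs.fasta)
    transcripts = read_transcripts(inputs.gtf)
    trio = extract_trio(read_ped(inputs.ped))

    called = list(read_vcf(inputs.vcf))
    logger.info("called: %d records", len(called))

    passing, failing = apply_hard_filters(called, inputs.thresholds)
    logger.info("hard_filter: %d pass, %d fail", len(passing), len(failing))

    annotations = annotate_all(passing, transcripts, reference)
    exonic = [
        r
        for r in passing
        if annotations[r.key].summary.category is not Category.NONCODING
    ]
    logger.info("exonic: %d records", len(exonic))

    conditional = recessive_trio_filter(exonic, trio)
    logger.info("conditional: %d records", len(conditional))

    if inputs.known_vcf is not None:
        known = read_known_sites(inputs.known_vcf)
        novel = subtract_known(conditional, known)
    else:
        known = set()
        novel = list(conditional)
    logger.info("novel: %d records", len(novel))

    candidates = [
        CandidateVariant(record=r, consequence=annotations[r.key].summary, known=False)
        for r in novel
    ]

    if inputs.scores is not None:
        scores = read_scores_tsv(inputs.scores)
        deleterious = deleterious_filter(
            candidates, scores, inputs.deleterious_threshold
        )
    else:
        logger.info("no score table supplied; deleterious filter is a no-op")
        deleterious = list(candidates)
    logger.info("deleterious: %d candidates", len(deleterious))

    flags = (
        read_inspection_tsv(inputs.inspection)
        if inputs.inspection is not None
        else None
    )
    inspected = inspection_filter(deleterious, flags)
    logger.info("inspection: %d candidates", len(inspected))

    stage_outputs = [
        ("called", called, None),
        ("hard_filter", passing, None),
        ("exonic", exonic, _breakdown(exonic, annotations)),
        ("conditional", conditional, _breakdown(conditional, annotations)),
        ("novel", novel, _breakdown(novel, annotations)),
        ("deleterious", [c.record for c in deleterious], None),
        ("inspection", [c.record for c in inspected], None),
    ]

    concordance_results = None
    final = inspected
    if inputs.cohort is not None:
        variants = read_variants_tsv(
            inputs.cohort_variants
            if inputs.cohort_variants is not None
            else inputs.cohort
        )
        table = read_cohort_tsv(inputs.cohort, variants)
        concordance_results = recessive_concordance(table)
        final = [
            c
            for c in inspected
            if c.key in concordance_results and concordance_results[c.key].concordant
        ]
        stage_outputs.append(("concordant", [c.record for c in final], None))
        logger.info("concordant: %d candidates", len(final))

    funnel = build_funnel(stage_outputs)
    stage_keys = {
        name: {r.key for r in records} for name, records, _ in stage_outputs
    }
    return PipelineResult(
        candidates=final,
        funnel=funnel,
        stage_keys=stage_keys,
        annotations=annotations,
        trio=trio,
        concordance=concordance_results,
    )


def write_candidates_tsv(candidates: list[CandidateVariant], path: str | Path) -> None:
    """Deterministic candidate table mirroring the annotation output."""
    header = (
        "chrom\tpos\tref\talt\tgene_id\ttranscript_id\tcategory\t"
        "cdna_name\tprotein_name\tknown\tscore\tinspection\n"
    )
    def fmt(value) -> str:
        return "." if value is None else str(value)

    with open(path, "w") as fh:
        fh.write(header)
        for c in sorted(candidates, key=lambda c: c.key):
            cons = c.consequence
            inspection = (
                "." if c.inspection_pass is None
                else ("pass" if c.inspection_pass else "fail")
            )
            fh.write(
                "\t".join(
                    [
                        c.record.chrom,
                        str(c.record.pos),
                        c.record.ref,
                        c.record.alt,
                        fmt(cons.gene_id),
                        fmt(cons.transcript_id),
                        cons.category.value,
                        fmt(cons.cdna_name),
                        fmt(cons.protein_name),
                        str(c.known).lower(),
                        fmt(c.deleterious_score),
                        inspection,
                    ]
                )
                + "\n"
            )
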