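"""The recessive trio filter and downstream candidate triage.

Under an autosomal recessive model with two healthy carrier parents, a
causal variant must be heterozygous in both parents and homozygous for
the alternate allele in the affected offspring.  Variants passing that
conditional filter are then stripped of known variation (exact
chrom/pos/ref/alt match), thresholded on an externally supplied
deleteriousness score (SIFT-style, deleterious < 0.05), and finally
checked against a manual-inspection pass/fail flag that models coverage
review in a genome browser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .consequence import Category, Consequence, NONCODING
from .model import GenotypeState, TrioSpec, VariantRecord

logger = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]

DELETERIOUS_THRESHOLD = 0.05


@dataclass
class CandidateVariant:
    record: VariantRecord
    consequence: Consequence = field(default=NONCODING)
    known: bool = False
    deleterious_score: Optional[float] = None
    inspection_pass: Optional[bool] = None

    @property
    def key(self) -> VariantKey:
        return self.record.key


def matches_recessive_trio(record: VariantRecord, trio: TrioSpec) -> bool:
    """Sire HET, dam HET, affected offspring HOM_ALT; MISSING excludes."""
    return (
        record.genotype(trio.sire_id).state() is GenotypeState.HET
        and record.genotype(trio.dam_id).state() is GenotypeState.HET
        and record.genotype(trio.offspring_id).state() is GenotypeState.HOM_ALT
    )


def recessive_trio_filter(
    records: Iterable[VariantRecord], trio: TrioSpec
) -> list[VariantRecord]:
    """Retain exactly the records matching the recessive trio pattern.

    A missing genotype in any of the three samples excludes the record:
    a partially genotyped site cannot demonstrate the pattern, and the
    model assumes a fully genotyped trio at candidate sites.
    """
    return [r for r in records if matches_recessive_trio(r, trio)]


def read_known_sites(path: str | Path) -> set[VariantKey]:
    """Load the known-variant set from a VCF as exact-allele keys."""
    from .io import read_vcf

    return {record.key for record in read_vcf(path)}


def subtract_known(
    records: Iterable[VariantRecord], known: set[VariantKey]
) -> list[VariantRecord]:
    """Drop records exactly matching a known site by (chrom, pos, ref, alt).

    Matching is allele-exact, not position-only: a novel allele at a known
    polymorphic position is still a candidate.
    """
    return [r for r in records if r.key not in known]


def mark_known(
    candidates: Iterable[CandidateVariant], known: set[VariantKey]
) -> list[CandidateVariant]:
    for c in candidates:
        c.known = c.key in known
    return [c for c in candidates]


def read_scores_tsv(path: str | Path) -> dict[VariantKey, float]:
    """Read a per-variant deleteriousness score table.

    Columns: chrom, pos, ref, alt, score; scores lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    scores: dict[VariantKey, float] = {}
    for row in df.itertuples(index=False):
        score = float(row.score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(
                f"score {score} at {row.chrom}:{row.pos} outside [0, 1]"
            )
        scores[(str(row.chrom), int(row.pos), row.ref, row.alt)] = score
    return scores


def deleterious_filter(
    candidates: Iterable[CandidateVariant],
    scores: dict[VariantKey, float],
    threshold: float = DELETERIOUS_THRESHOLD,
) -> list[CandidateVariant]:
    """Retain missense candidates with score strictly below the threshold.

    Only missense substitutions are eligible for scoring — the score
    models the effect of an amino-acid change, so silent and other
    categories are dropped here, as are missense candidates without a
    score (with a warning).
    """
    kept: list[CandidateVariant] = []
    for c in candidates:
        if c.consequence.category is not Category.MISSENSE:
            continue
        score = scores.get(c.key)
        c.deleterious_score = score
        if score is None:
            logger.warning(
                "no deleteriousness score for %s:%d %s>%s; dropped",
                *c.key,
            )
            continue
        if score < threshold:
            kept.append(c)
    return kept


def read_inspection_tsv(path: str | Path) -> dict[VariantKey, bool]:
    """Read manual-inspection flags: chrom, pos, ref, alt, verdict (pass|fail)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    flags: dict[VariantKey, bool] = {}
    for row in df.itertuples(index=False):
        verdict = str(row.verdict).strip().lower()
        if verdict not in ("pass", "fail"):
            raise ValueError(f"inspection verdict must be pass|fail, got {verdict!r}")
        flags[(str(row.chrom), int(row.pos), row.ref, row.alt)] = verdict == "pass"
    return flags


def inspection_filter(
    candidates: Iterable[CandidateVariant],
    flags: Optional[dict[VariantKey, bool]],
) -> list[CandidateVariant]:
    """Retain candidates whose externally supplied inspection flag is pass.

    The manual review of read alignments is modelled as an input, not a
    computation.  With no flag file the filter is the identity; a candidate
    without a flag is kept (uninspected, not refuted).
    """
    candidates = list(candidates)
    if flags is None:
        logger.info("no inspection flags supplied; inspection filter is a no-op")
        return candidates
    kept: list[CandidateVariant] = []
    for c in candidates:
        c.inspection_pass = flags.get(c.key)
        if c.inspection_pass is False:
            continue
        kept.append(c)
    return kept
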