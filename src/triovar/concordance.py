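"""Validation-stage logic: orthogonal trio confirmation, case/control
concordance under the recessive model, and cross-breed panel exclusion.

A variant is concordant with a recessive disorder when every affected
individual is homozygous for the alternate allele and no healthy control
is — heterozygous carriers among the controls are expected and allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .model import GenotypeState, TrioSpec, TriovarError
from .segregation import CandidateVariant, VariantKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str] = None

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def column(self) -> str:
        return f"{self.chrom}:{self.pos}"


def parse_genotype_string(
    genotype: str, ref: str, alt: str
) -> GenotypeState:
    """Interpret an unordered allele-pair string like ``G/T``.

    ``G/T`` and ``T/G`` are the same genotype; ``./.`` (or empty) is
    missing.  Alleles outside the variant's ref/alt alphabet are an error.
    """
    genotype = genotype.strip()
    if not genotype or genotype in (".", "./."):
        return GenotypeState.MISSING
    alleles = genotype.split("/")
    if len(alleles) != 2:
        raise TriovarError(f"genotype string {genotype!r} is not an allele pair")
    if any(a == "." for a in alleles):
        return GenotypeState.MISSING
    for a in alleles:
        if a not in (ref, alt):
            raise TriovarError(
                f"allele {a!r} in genotype {genotype!r} is neither ref {ref} nor alt {alt}"
            )
    n_alt = sum(a == alt for a in alleles)
    return (
        GenotypeState.HOM_REF,
        GenotypeState.HET,
        GenotypeState.HOM_ALT,
    )[n_alt]


@dataclass
class CohortTable:
    """Variants x samples genotype matrix with case/control labels."""

    variants: list[CohortVariant]
    samples: list[tuple[str, str]]  # (sample_id, phenotype in {case, control})
    genotypes: dict[tuple[str, VariantKey], GenotypeState]
    reference_sample: Optional[str] = None

    def __post_init__(self) -> None:
        for sample_id, _ in self.samples:
            for variant in self.variants:
                if (sample_id, variant.key) not in self.genotypes:
                    raise TriovarError(
                        f"genotype matrix missing cell ({sample_id}, {variant.column})"
                    )

    def state(self, sample_id: str, variant: CohortVariant) -> GenotypeState:
        return self.genotypes[(sample_id, variant.key)]

    def cases(self) -> list[str]:
        return [s for s, p in self.samples if p == "case"]

    def controls(self) -> list[str]:
        return [s for s, p in self.samples if p == "control"]

    def variant_by_key(self, key: VariantKey) -> CohortVariant:
        for v in self.variants:
            if v.key == key:
                return v
        raise TriovarError(f"variant {key} absent from cohort table")


@dataclass
class ConcordanceResult:
    variant: CohortVariant
    failure_reasons: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def concordant(self) -> bool:
        return not self.failure_reasons


def read_variants_tsv(path: str | Path) -> list[CohortVariant]:
    """Variant metadata table: chrom, pos, ref, alt, gene."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CohortVariant(
            chrom=str(r.chrom), pos=int(r.pos), ref=r.ref, alt=r.alt,
            gene_id=getattr(r, "gene", None),
        )
        for r in df.itertuples(index=False)
    ]


def read_cohort_tsv(
    path: str | Path, variants: list[CohortVariant]
) -> CohortTable:
    """Read a cohort genotype matrix.

    First column is the sample id, second the phenotype (``case``,
    ``control`` or ``reference``), then one column per variant keyed
    ``chrom:pos`` holding unordered allele-pair genotype strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    by_column = {v.column: v for v in variants}
    missing_cols = [c for c in by_column if c not in df.columns]
    if missing_cols:
        raise TriovarError(
            f"{path}: cohort table lacks variant columns: {', '.join(missing_cols)}"
        )
    samples: list[tuple[str, str]] = []
    genotypes: dict[tuple[str, VariantKey], GenotypeState] = {}
    reference_sample = None
    for _, row in df.iterrows():
        sample_id = str(row.iloc[0])
        phenotype = str(row.iloc[1]).strip().lower()
        if phenotype == "reference":
            reference_sample = sample_id
            continue
        if phenotype not in ("case", "control"):
            raise TriovarError(
                f"{path}: phenotype for {sample_id!r} must be case/control/reference, "
                f"got {phenotype!r}"
            )
        samples.append((sample_id, phenotype))
        for column, variant in by_column.items():
            value = row[column]
            genotypes[(sample_id, variant.key)] = parse_genotype_string(
                "" if pd.isna(value) else str(value), variant.ref, variant.alt
            )
    return CohortTable(
        variants=list(variants),
        samples=samples,
        genotypes=genotypes,
        reference_sample=reference_sample,
    )


def confirm_trio_genotypes(
    wgs_calls: dict[VariantKey, dict[str, GenotypeState]],
    orthogonal_calls: dict[VariantKey, dict[str, GenotypeState]],
    trio: TrioSpec,
) -> dict[VariantKey, ConcordanceResult]:
    """Confirm WGS trio genotypes against an orthogonal assay.

    A variant is confirmed when the orthogonal genotypes independently
    satisfy the recessive pattern: sire HET, dam HET, offspring HOM_ALT.
    Otherwise it is refuted, with the offending samples listed.
    """
    results: dict[VariantKey, ConcordanceResult] = {}
    expectations = (
        (trio.sire_id, GenotypeState.HET, "sire must be het"),
        (trio.dam_id, GenotypeState.HET, "dam must be het"),
        (trio.offspring_id, GenotypeState.HOM_ALT, "offspring must be hom-alt"),
    )
    for key in wgs_calls:
        chrom, pos, ref, alt = key
        variant = CohortVariant(chrom, pos, ref, alt)
        result = ConcordanceResult(variant=variant)
        ortho = orthogonal_calls.get(key)
        if ortho is None:
            result.failure_reasons.append(("*", "absent", "no orthogonal genotypes"))
        else:
            for sample_id, expected, constraint in expectations:
                observed = ortho.get(sample_id, GenotypeState.MISSING)
                if observed is not expected:
                    result.failure_reasons.append(
                        (sample_id, observed.value, constraint)
                    )
        results[key] = result
    return results


def recessive_concordance(table: CohortTable) -> dict[VariantKey, ConcordanceResult]:
    """Per-variant case/control concordance under the recessive model.

    Concordant iff every case is HOM_ALT and no control is HOM_ALT.
    Carrier (HET) controls are allowed.  A missing case genotype breaks
    concordance (the pattern cannot be demonstrated); a missing control
    genotype is ignored with a warning.
    """
    cases, controls = table.cases(), table.controls()
    if not cases or not controls:
        raise TriovarError(
            f"concordance requires >=1 case and >=1 control, got "
            f"{len(cases)} cases / {len(controls)} controls"
        )
    results: dict[VariantKey, ConcordanceResult] = {}
    for variant in table.variants:
        result = ConcordanceResult(variant=variant)
        for sample_id in cases:
            state = table.state(sample_id, variant)
            if state is GenotypeState.MISSING:
                result.failure_reasons.append(
                    (sample_id, "missing", "case genotype missing")
                )
            elif state is not GenotypeState.HOM_ALT:
                result.failure_reasons.append(
                    (sample_id, state.value, "case must be hom-alt")
                )
        for sample_id in controls:
            state = table.state(sample_id, variant)
            if state is GenotypeState.MISSING:
                logger.warning(
                    "control %s has a missing genotype at %s; ignored",
                    sample_id,
                    variant.column,
                )
            elif state is GenotypeState.HOM_ALT:
                result.failure_reasons.append(
                    (sample_id, state.value, "control must not be hom-alt")
                )
        results[variant.key] = result
    return results


def panel_exclusion(
    candidates: Iterable[CandidateVariant], panel: Optional[CohortTable]
) -> dict[VariantKey, bool]:
    """Flag candidates excluded by a panel of unaffected genomes.

    A candidate is excluded iff any unaffected panel sample is homozygous
    for the alternate allele — a healthy homozygote is incompatible with a
    fully penetrant recessive causal allele.  Heterozygous carriers do not
    exclude.  An empty or absent panel excludes nothing.
    """
    flags: dict[VariantKey, bool] = {}
    for c in candidates:
        excluded = False
        if panel is not None:
            try:
                variant = panel.variant_by_key(c.key)
            except TriovarError:
                variant = None
            if variant is not None:
                for sample_id, phenotype in panel.samples:
                    if phenotype != "control":
                        continue
                    if panel.state(sample_id, variant) is GenotypeState.HOM_ALT:
                        excluded = True
                        break
        flags[c.key] = excluded
    return flags
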