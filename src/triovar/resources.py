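"""Packaged reference tables: the published Sanger-validation genotypes
for the seven candidate variants of canine hereditary footpad
hyperkeratosis (HFH), on CanFam3.1 coordinates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .concordance import (
    CohortTable,
    CohortVariant,
    parse_genotype_string,
    read_cohort_tsv,
    read_variants_tsv,
)
from .model import GenotypeState, TrioSpec
from .segregation import VariantKey


def _data_path(name: str):
    return resources.files("triovar").joinpath("data", name)


def load_hfh_variants() -> list[CohortVariant]:
    """The seven HFH candidate variants in six genes (incl. FAM83G c.155G>C)."""
    with resources.as_file(_data_path("hfh_candidate_variants.tsv")) as p:
        return read_variants_tsv(p)


def load_hfh_trio_genotypes() -> tuple[
    dict[VariantKey, dict[str, GenotypeState]], TrioSpec
]:
    """Sanger genotypes of the sequenced family trio at the candidate variants.

    Returns the per-variant sample -> genotype-state map and the trio
    specification (samples named ``sire``, ``dam``, ``offspring``).
    """
    variants = load_hfh_variants()
    with resources.as_file(_data_path("hfh_trio_sanger.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    calls: dict[VariantKey, dict[str, GenotypeState]] = {v.key: {} for v in variants}
    for _, row in df.iterrows():
        sample_id = str(row.iloc[0])
        for v in variants:
            calls[v.key][sample_id] = parse_genotype_string(
                str(row[v.column]), v.ref, v.alt
            )
    trio = TrioSpec(sire_id="sire", dam_id="dam", offspring_id="offspring")
    return calls, trio


def load_hfh_cohort_table() -> CohortTable:
    """Case/control Sanger genotypes: 8 additional HFH cases, 16 healthy controls."""
    variants = load_hfh_variants()
    with resources.as_file(_data_path("hfh_cohort_sanger.tsv")) as p:
        return read_cohort_tsv(p, variants)
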