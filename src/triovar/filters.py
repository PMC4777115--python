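"""Site-level hard filtering of raw variant calls.

Implements the standard GATK-style hard-filter recipe: a site fails when
MQ < 40, QD < 2.0, or — class-dependently — FS > 60.0 (SNV) / 200.0
(indel) or ReadPosRankSum < -8.0 (SNV) / -20.0 (indel).  All comparisons
are strict, so a value exactly at a threshold passes.  An absent metric
never triggers its filter: callers only emit ReadPosRankSum at sites with
heterozygous calls, so absence means "not applicable", not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model import VariantRecord


@dataclass(frozen=True)
class FilterThresholds:
    mq_min: float = 40.0
    qd_min: float = 2.0
    fs_max_snv: float = 60.0
    fs_max_indel: float = 200.0
    rprs_min_snv: float = -8.0
    rprs_min_indel: float = -20.0

    def __post_init__(self) -> None:
        if self.fs_max_indel < self.fs_max_snv:
            raise ValueError("fs_max_indel must be >= fs_max_snv")
        if self.rprs_min_indel > self.rprs_min_snv:
            raise ValueError("rprs_min_indel must be <= rprs_min_snv")


#: Filter labels in the GATK VariantFiltration naming style.
LABEL_MQ = "MQ40"
LABEL_QD = "QD2"
LABEL_FS_SNV = "FS60"
LABEL_FS_INDEL = "FS200"
LABEL_RPRS_SNV = "ReadPosRankSum-8"
LABEL_RPRS_INDEL = "ReadPosRankSum-20"


def failed_filters(record: VariantRecord, thresholds: FilterThresholds) -> set[str]:
    """Labels of every hard filter the record violates (empty = pass)."""
    m = record.metrics
    labels: set[str] = set()
    if m.mq is not None and m.mq < thresholds.mq_min:
        labels.add(LABEL_MQ)
    if m.qd is not None and m.qd < thresholds.qd_min:
        labels.add(LABEL_QD)
    if record.is_snv:
        if m.fs is not None and m.fs > thresholds.fs_max_snv:
            labels.add(LABEL_FS_SNV)
        if (
            m.read_pos_rank_sum is not None
            and m.read_pos_rank_sum < thresholds.rprs_min_snv
        ):
            labels.add(LABEL_RPRS_SNV)
    else:
        if m.fs is not None and m.fs > thresholds.fs_max_indel:
            labels.add(LABEL_FS_INDEL)
        if (
            m.read_pos_rank_sum is not None
            and m.read_pos_rank_sum < thresholds.rprs_min_indel
        ):
            labels.add(LABEL_RPRS_INDEL)
    return labels


def apply_hard_filters(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition records into (passing, failing).

    Failing records are annotated with the label of every violated filter
    and retained in the second return value — flagged, not deleted, as
    VariantFiltration does — so they can be written out with a populated
    FILTER column.  Passing records get an empty ``filter_status``.
    """
    thresholds = thresholds or FilterThresholds()
    passing: list[VariantRecord] = []
    failing: list[VariantRecord] = []
    for record in records:
        labels = failed_filters(record, thresholds)
        record.filter_status = labels
        (failing if labels else passing).append(record)
    return passing, failing
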