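"""Machine-readable filtering-funnel report.

Each pipeline stage records how many SNVs and indels survive it; counts
must be non-increasing along the funnel and per-category breakdowns
(missense/nonsense/silent) must sum to the stage total for coding SNVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .model import TriovarError, VariantClass, VariantRecord

#: Canonical stage order of the filtering pipeline.
STAGE_ORDER = (
    "called",
    "hard_filter",
    "exonic",
    "conditional",
    "novel",
    "deleterious",
    "inspection",
    "concordant",
)


@dataclass
class FunnelStage:
    name: str
    snv: int
    indel: int
    removed: int = 0
    breakdown: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.snv + self.indel


@dataclass
class FunnelReport:
    stages: list[FunnelStage]

    def validate(self) -> None:
        previous: Optional[FunnelStage] = None
        for stage in self.stages:
            if previous is not None:
                if stage.total > previous.total:
                    raise TriovarError(
                        f"funnel stage {stage.name!r} ({stage.total}) exceeds "
                        f"predecessor {previous.name!r} ({previous.total})"
                    )
                expected_removed = previous.total - stage.total
                if stage.removed != expected_removed:
                    raise TriovarError(
                        f"funnel stage {stage.name!r}: removed={stage.removed} "
                        f"but predecessor difference is {expected_removed}"
                    )
            previous = stage

    def stage(self, name: str) -> FunnelStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = [
            {
                "stage": s.name,
                "snv": s.snv,
                "indel": s.indel,
                "removed": s.removed,
                "breakdown": s.breakdown,
            }
            for s in self.stages
        ]
        text = json.dumps(payload, indent=2, sort_keys=False) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path: Optional[str | Path] = None) -> str:
        lines = ["stage\tsnv\tindel\tremoved\tbreakdown"]
        for s in self.stages:
            breakdown = ";".join(f"{k}={v}" for k, v in sorted(s.breakdown.items()))
            lines.append(f"{s.name}\t{s.snv}\t{s.indel}\t{s.removed}\t{breakdown}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _count(records: Iterable[VariantRecord]) -> tuple[int, int]:
    snv = indel = 0
    for r in records:
        if r.variant_class is VariantClass.SNV:
            snv += 1
        else:
            indel += 1
    return snv, indel


def build_funnel(
    stage_outputs: list[tuple[str, list[VariantRecord], Optional[dict[str, int]]]],
) -> FunnelReport:
    """Build and validate a funnel from ordered (name, records, breakdown) stages."""
    stages: list[FunnelStage] = []
    previous_total: Optional[int] = None
    for name, records, breakdown in stage_outputs:
        snv, indel = _count(records)
        removed = 0 if previous_total is None else previous_total - (snv + indel)
        stage = FunnelStage(
            name=name, snv=snv, indel=indel, removed=removed, breakdown=breakdown or {}
        )
        if breakdown:
            if sum(breakdown.values()) != snv + indel:
                raise TriovarError(
                    f"funnel stage {name!r}: breakdown sums to "
                    f"{sum(breakdown.values())}, stage total is {snv + indel}"
                )
        stages.append(stage)
        previous_total = snv + indel
    report = FunnelReport(stages=stages)
    report.validate()
    return report
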