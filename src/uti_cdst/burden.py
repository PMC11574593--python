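"""Antibiotic-burden accounting: days of therapy by appropriateness and class.

Days of therapy (DOT) are per-agent calendar days summed over agents: a
patient on two agent classes for three days each contributes six days.
Appropriateness is a record-level property — every course of an
inappropriately treated patient counts as unjustified — because the study
stratifies days by patient, not by course.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from pydantic import BaseModel, Field, model_validator

from .models import PatientRecord


class BurdenSummary(BaseModel):
    """Days-of-therapy totals, globally and per antibiotic class."""

    total_days: int = Field(ge=0)
    unjustified_days: int = Field(ge=0)
    by_class: dict[str, tuple[int, int]]  # agent_class -> (total, unjustified)

    @model_validator(mode="after")
    def _coherent(self) -> "BurdenSummary":
        if self.unjustified_days > self.total_days:
            raise ValueError("unjustified_days cannot exceed total_days")
        for agent, (total, unjustified) in self.by_class.items():
            if unjustified > total:
                raise ValueError(f"class {agent!r}: unjustified days exceed total")
        if sum(total for total, _ in self.by_class.values()) != self.total_days:
            raise ValueError("per-class totals must sum to total_days")
        if sum(u for _, u in self.by_class.values()) != self.unjustified_days:
            raise ValueError("per-class unjustified days must sum to unjustified_days")
        return self


def burden(records: Sequence[PatientRecord], inappropriate: Sequence[bool]) -> BurdenSummary:
    """Aggregate days of therapy, stratified by appropriateness and class."""
    if len(records) != len(inappropriate):
        raise ValueError(
            f"record/flag length mismatch: {len(records)} vs {len(inappropriate)}"
        )
    totals: dict[str, int] = defaultdict(int)
    unjustified: dict[str, int] = defaultdict(int)
    for record, flag in zip(records, inappropriate):
        for course in record.courses:
            totals[course.agent_class] += course.days_of_therapy
            if flag:
                unjustified[course.agent_class] += course.days_of_therapy
    return BurdenSummary(
        total_days=sum(totals.values()),
        unjustified_days=sum(unjustified.values()),
        by_class={agent: (totals[agent], unjustified.get(agent, 0)) for agent in sorted(totals)},
    )


def reduction_fraction(summary: BurdenSummary) -> float:
    """Fraction of all antibiotic days avoidable by withholding unjustified
    treatment — the tool's potential reduction in antibiotic use."""
    if summary.total_days == 0:
        raise ValueError("reduction fraction undefined for an empty burden (total_days=0)")
    return summary.unjustified_days / summary.total_days
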