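"""Skip-pattern logic: applicable indicators per record, response validation,
and maximal open-gate question counts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .standard import AGE_GROUPS, IndicatorRegistry

__all__ = [
    "RESPONSES",
    "VARecord",
    "ValidationReport",
    "applicable_indicators",
    "validate_record",
    "max_question_count",
]

RESPONSES = ("yes", "no", "dont_know", "not_applicable")
SEXES = ("male", "female", "unknown")


@dataclass
class VARecord:
    """One decedent's interview: age group, sex, and indicator responses."""

    record_id: str
    age_group: str
    sex: str = "unknown"
    responses: dict[str, str] = field(default_factory=dict)
    free_text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group: {self.age_group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex: {self.sex!r}")
        for iid, resp in self.responses.items():
            if resp not in RESPONSES:
                raise ValueError(f"{iid}: bad response {resp!r}")

    def endorsed(self) -> set[str]:
        return {i for i, r in self.responses.items() if r == "yes"}

    def denied(self) -> set[str]:
        return {i for i, r in self.responses.items() if r == "no"}


def applicable_indicators(
    age_group: str,
    responses: dict[str, str],
    registry: IndicatorRegistry,
) -> set[str]:
    """Fixpoint of the gating relation for one record.

    Level-1 CoD items and all gate-free (personal/respondent/context)
    items of the age group are always applicable; a level-k item is
    applicable iff its parent is applicable and answered "yes".
    "dont_know" and missing answers close a gate.  Monotone: adding a
    "yes" never removes applicability.
    """
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group: {age_group!r}")
    applicable: set[str] = set()
    # levels are strictly increasing along parent chains, so one pass per
    # level reaches the fixpoint
    for level in (1, 2, 3, 4):
        for ind in registry.for_age_group(age_group, "cod_related"):
            if ind.skip_level != level:
                continue
            if level == 1:
                applicable.add(ind.indicator_id)
            elif ind.parent_id in applicable and responses.get(ind.parent_id) == "yes":
                applicable.add(ind.indicator_id)
    for ind in registry.for_age_group(age_group):
        if ind.category != "cod_related":
            applicable.add(ind.indicator_id)
    return applicable


@dataclass
class ValidationReport:
    violations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def add(self, indicator_id: str, rule: str, message: str) -> None:
        self.violations.append((indicator_id, rule, message))


def validate_record(record: VARecord, registry: IndicatorRegistry) -> ValidationReport:
    """Flag skip-pattern and block-consistency violations (report-only).

    (a) substantive answers on non-applicable items, (b) missing answers
    on applicable items, (c) maternal-block answers on male or
    non-adult records.
    """
    report = ValidationReport()
    applicable = applicable_indicators(record.age_group, record.responses, registry)
    group_ids = {i.indicator_id for i in registry.for_age_group(record.age_group)}

    for iid, resp in record.responses.items():
        if iid not in registry:
            report.add(iid, "unknown_indicator", "not in the registry")
            continue
        if iid not in group_ids:
            report.add(iid, "age_group",
                       f"not applicable to age group {record.age_group}")
            continue
        if iid not in applicable and resp in ("yes", "no", "dont_know"):
            report.add(iid, "skip_pattern",
                       "substantive answer on an item closed by its gate")
    for iid in applicable:
        resp = record.responses.get(iid)
        if resp is None:
            report.add(iid, "missing", "applicable item left unanswered")
        elif resp == "not_applicable":
            report.add(iid, "skip_pattern",
                       "applicable item marked not_applicable")

    maternal_forbidden = record.sex == "male" or record.age_group != "adult"
    if maternal_forbidden:
        for ind in registry.all_indicators():
            if not ind.maternal:
                continue
            resp = record.responses.get(ind.indicator_id)
            if resp == "yes" or (
                resp in ("no", "dont_know") and not ind.parent_id == ""
            ):
                report.add(ind.indicator_id, "maternal_block",
                           "maternal item answered on a "
                           f"{record.sex} {record.age_group} record")
    return report


def max_question_count(
    age_group: str, profile: str, registry: IndicatorRegistry
) -> int:
    """CoD-related item count on the maximal gate-open path for a profile.

    ``generic`` closes the maternal screen's descendants; ``maternal``
    (adult only) opens every gate including the maternal block.
    """
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group: {age_group!r}")
    if profile not in ("generic", "maternal"):
        raise ValueError(f"unknown profile: {profile!r}")
    if profile == "maternal" and age_group != "adult":
        raise ValueError("maternal profile applies only to adult deaths")
    items = registry.for_age_group(age_group, "cod_related")
    if profile == "generic":
        items = [i for i in items if not (i.maternal and i.parent_id)]
    return len(items)
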