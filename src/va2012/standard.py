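"""Packaged 2012 VA standard: cause list, indicator registry, subsumption map.

All artifacts ship as JSON under ``va2012/data`` and are validated
against the published structural constants on load.  The indicator
registry is a stub instrument — stable ids and labels satisfying every
printed count constraint — and can be swapped for the official item
list without code change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .icd import ICDCode, ICDRange, MappingRule, build_rules, parse_icd, parse_range

__all__ = [
    "AGE_GROUPS",
    "CauseCategory",
    "CauseList",
    "IndicatorDef",
    "IndicatorRegistry",
    "SubsumptionEntry",
    "StandardConstants",
    "StandardLoadError",
    "Violation",
    "load_cause_list",
    "load_indicator_registry",
    "load_subsumption_map",
    "load_constants",
    "registry_consistency_report",
]

AGE_GROUPS = ("neonate", "child", "adult")
INDICATOR_CATEGORIES = ("cod_related", "personal", "respondent", "context")

UNKNOWN_CAUSE = "VA-99"


class StandardLoadError(ValueError):
    """Packaged data failed schema or consistency validation."""


@dataclass(frozen=True)
class ToICDEntry:
    code: ICDCode
    context: str  # "" for the unlabeled (default) printed code


@dataclass(frozen=True)
class CauseCategory:
    """One VA cause category with its certification and source ICD codes."""

    va_code: str
    title: str
    group_code: str
    to_icd: tuple[ToICDEntry, ...]
    from_icd: tuple[ICDRange, ...]
    notes: str = ""

    @property
    def residual(self) -> bool:
        return self.va_code in ("VAs-98", UNKNOWN_CAUSE) or self.va_code.endswith(".99")


class CauseList:
    """Ordered cause categories plus the flattened mapping rules.

    ``leaf_categories`` are the 62 cause categories (the VA-99 unknown
    sentinel is carried for mapping and assignment but not counted).
    """

    def __init__(self, causes: list[CauseCategory], groups: dict[str, str]):
        self._causes = causes
        self.groups = groups
        self._by_code = {c.va_code: c for c in causes}
        if len(self._by_code) != len(causes):
            raise StandardLoadError("duplicate va_code in cause list")
        self.rules: list[MappingRule] = build_rules(self)

    def all_categories(self) -> list[CauseCategory]:
        return list(self._causes)

    def leaf_categories(self) -> list[CauseCategory]:
        return [c for c in self._causes if c.va_code != UNKNOWN_CAUSE]

    def leaf_codes(self) -> list[str]:
        return [c.va_code for c in self.leaf_categories()]

    def group_members(self, group_code: str) -> list[CauseCategory]:
        return [c for c in self._causes if c.group_code == group_code]

    def __len__(self) -> int:
        return len(self.leaf_categories())

    def __contains__(self, va_code: str) -> bool:
        return va_code in self._by_code

    def __getitem__(self, va_code: str) -> CauseCategory:
        try:
            return self._by_code[va_code]
        except KeyError:
            raise KeyError(f"unknown VA cause code: {va_code!r}") from None

    def to_payload(self) -> dict:
        """Serialize back to the packaged JSON structure (round-trippable)."""
        return {
            "groups": [
                {"group_code": g, "title": t} for g, t in self.groups.items()
            ],
            "causes": [
                {
                    "va_code": c.va_code,
                    "group_code": c.group_code,
                    "title": c.title,
                    "to_icd": [
                        {"code": str(e.code), "context": e.context} for e in c.to_icd
                    ],
                    "from_icd": [str(r) for r in c.from_icd],
                    "notes": c.notes,
                }
                for c in self._causes
            ],
        }


@dataclass(frozen=True)
class IndicatorDef:
    """A questionnaire indicator stub with skip-level and age applicability."""

    indicator_id: str
    label: str
    category: str
    skip_level: Optional[int]
    age_groups: frozenset[str]
    parent_id: str = ""
    maternal: bool = False


class IndicatorRegistry:
    """Indicator set plus skip topology, validated against printed counts."""

    def __init__(self, indicators: list[IndicatorDef]):
        self._indicators = indicators
        self._by_id = {i.indicator_id: i for i in indicators}
        if len(self._by_id) != len(indicators):
            raise StandardLoadError("duplicate indicator_id in registry")
        self._children: dict[str, list[str]] = {}
        for ind in indicators:
            if ind.parent_id:
                self._children.setdefault(ind.parent_id, []).append(ind.indicator_id)
        self._validate_topology()

    def _validate_topology(self) -> None:
        for ind in self._indicators:
            if ind.category == "cod_related":
                if ind.skip_level not in (1, 2, 3, 4):
                    raise StandardLoadError(
                        f"{ind.indicator_id}: cod_related needs skip_level 1-4"
                    )
                if ind.skip_level == 1 and ind.parent_id:
                    raise StandardLoadError(
                        f"{ind.indicator_id}: level-1 item must not have a parent"
                    )
                if ind.skip_level > 1:
                    parent = self._by_id.get(ind.parent_id)
                    if parent is None:
                        raise StandardLoadError(
                            f"{ind.indicator_id}: parent {ind.parent_id!r} missing"
                        )
                    if parent.skip_level != ind.skip_level - 1:
                        raise StandardLoadError(
                            f"{ind.indicator_id}: parent skip_level must be "
                            f"{ind.skip_level - 1}, got {parent.skip_level}"
                        )
                    if not ind.age_groups <= parent.age_groups:
                        raise StandardLoadError(
                            f"{ind.indicator_id}: age groups exceed parent's"
                        )
            elif ind.skip_level is not None or ind.parent_id:
                raise StandardLoadError(
                    f"{ind.indicator_id}: non-CoD items are gate-free"
                )
            if not ind.age_groups or not ind.age_groups <= set(AGE_GROUPS):
                raise StandardLoadError(f"{ind.indicator_id}: bad age groups")

    # --- accessors -------------------------------------------------------

    def all_indicators(self) -> list[IndicatorDef]:
        return list(self._indicators)

    def __getitem__(self, indicator_id: str) -> IndicatorDef:
        try:
            return self._by_id[indicator_id]
        except KeyError:
            raise KeyError(f"unknown indicator: {indicator_id!r}") from None

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    def children_of(self, indicator_id: str) -> list[str]:
        return list(self._children.get(indicator_id, []))

    def is_gate(self, indicator_id: str) -> bool:
        return indicator_id in self._children

    def for_age_group(
        self, age_group: str, category: Optional[str] = None
    ) -> list[IndicatorDef]:
        if age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group: {age_group!r}")
        return [
            i
            for i in self._indicators
            if age_group in i.age_groups
            and (category is None or i.category == category)
        ]

    def cod_related(self) -> list[IndicatorDef]:
        return [i for i in self._indicators if i.category == "cod_related"]

    def distinct_count(self, level: Optional[int] = None) -> int:
        return sum(
            1
            for i in self.cod_related()
            if level is None or i.skip_level == level
        )

    def group_level_count(self, age_group: str, level: int) -> int:
        return sum(
            1
            for i in self.for_age_group(age_group, "cod_related")
            if i.skip_level == level
        )

    def to_payload(self) -> dict:
        return {
            "indicators": [
                {
                    "indicator_id": i.indicator_id,
                    "label": i.label,
                    "category": i.category,
                    "skip_level": i.skip_level,
                    "age_groups": sorted(i.age_groups),
                    "parent_id": i.parent_id,
                    "maternal": i.maternal,
                }
                for i in self._indicators
            ]
        }


@dataclass(frozen=True)
class SubsumptionEntry:
    """A 2007-standard cause absorbed by a 2012 category."""

    cause_2007: str
    target_va_code: str


@dataclass(frozen=True)
class StandardConstants:
    """Printed structural constants of the 2007→2012 simplification."""

    n_causes_2007: int
    n_causes_2012: int
    n_indicators_2007: int
    n_indicators_2012: int
    n_retained: int
    n_new: int
    n_excluded: int
    n_subsumed: int
    cod_related_by_group: dict
    distinct_by_level: dict
    non_cod_by_group: dict
    group_totals: dict


# --- loading -------------------------------------------------------------


def _data_path(name: str, data_dir: Optional[Path] = None) -> Path:
    if data_dir is not None:
        return Path(data_dir) / name
    return Path(str(resources.files("va2012").joinpath("data", name)))


def _load_json(name: str, data_dir: Optional[Path] = None) -> dict:
    path = _data_path(name, data_dir)
    try:
        return json.loads(path.read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise StandardLoadError(f"packaged data file missing: {path}") from None
    except json.JSONDecodeError as exc:
        raise StandardLoadError(f"{path}: invalid JSON ({exc})") from None


def load_cause_list(data_dir: Optional[Path] = None) -> CauseList:
    """Load and validate the packaged 62-category cause list."""
    payload = _load_json("cause_list.json", data_dir)
    groups = {g["group_code"]: g["title"] for g in payload.get("groups", [])}
    causes: list[CauseCategory] = []
    for row in payload.get("causes", []):
        code = row.get("va_code", "<missing>")
        try:
            to_icd = tuple(
                ToICDEntry(parse_icd(e["code"]), e.get("context", ""))
                for e in row["to_icd"]
            )
            from_icd = tuple(parse_range(r) for r in row["from_icd"])
            cause = CauseCategory(
                va_code=row["va_code"],
                title=row["title"],
                group_code=row["group_code"],
                to_icd=to_icd,
                from_icd=from_icd,
                notes=row.get("notes", ""),
            )
        except (KeyError, ValueError) as exc:
            raise StandardLoadError(f"cause list row {code!r}: {exc}") from None
        if cause.group_code not in groups:
            raise StandardLoadError(f"cause list row {code!r}: unknown group")
        if not cause.to_icd or not cause.from_icd:
            raise StandardLoadError(f"cause list row {code!r}: empty ICD column")
        causes.append(cause)
    cause_list = CauseList(causes, groups)
    if len(cause_list) != 62:
        raise StandardLoadError(
            f"expected 62 leaf cause categories, found {len(cause_list)}"
        )
    return cause_list


def load_indicator_registry(data_dir: Optional[Path] = None) -> IndicatorRegistry:
    """Load the packaged indicator registry and check its count invariants."""
    payload = _load_json("indicator_registry.json", data_dir)
    indicators = []
    for row in payload.get("indicators", []):
        iid = row.get("indicator_id", "<missing>")
        try:
            if row["category"] not in INDICATOR_CATEGORIES:
                raise ValueError(f"bad category {row['category']!r}")
            indicators.append(
                IndicatorDef(
                    indicator_id=row["indicator_id"],
                    label=row["label"],
                    category=row["category"],
                    skip_level=row.get("skip_level"),
                    age_groups=frozenset(row["age_groups"]),
                    parent_id=row.get("parent_id", ""),
                    maternal=bool(row.get("maternal", False)),
                )
            )
        except (KeyError, ValueError) as exc:
            raise StandardLoadError(f"indicator row {iid!r}: {exc}") from None
    registry = IndicatorRegistry(indicators)
    constants = load_constants(data_dir)
    violations = _registry_count_violations(registry, constants)
    if violations:
        deltas = "; ".join(str(v) for v in violations)
        raise StandardLoadError(f"registry count mismatch: {deltas}")
    return registry


def load_subsumption_map(
    data_dir: Optional[Path] = None, cause_list: Optional[CauseList] = None
) -> list[SubsumptionEntry]:
    """Load the 27-entry 2007→2012 subsumption map; all targets must resolve."""
    payload = _load_json("subsumption_map.json", data_dir)
    entries = [
        SubsumptionEntry(row["cause_2007"], row["target_va_code"])
        for row in payload.get("entries", [])
    ]
    if len(entries) != 27:
        raise StandardLoadError(f"expected 27 subsumption entries, got {len(entries)}")
    if cause_list is None:
        cause_list = load_cause_list(data_dir)
    for entry in entries:
        if entry.target_va_code not in cause_list:
            raise StandardLoadError(
                f"subsumption target {entry.target_va_code!r} "
                f"({entry.cause_2007!r}) not in the 2012 cause list"
            )
    return entries


def load_constants(data_dir: Optional[Path] = None) -> StandardConstants:
    payload = _load_json("constants.json", data_dir)
    try:
        return StandardConstants(**payload)
    except TypeError as exc:
        raise StandardLoadError(f"constants.json: {exc}") from None


# --- consistency reporting ----------------------------------------------


@dataclass(frozen=True)
class Violation:
    constant: str
    expected: object
    observed: object

    def __str__(self) -> str:
        return f"{self.constant}: expected {self.expected}, observed {self.observed}"


def _registry_count_violations(
    registry: IndicatorRegistry, constants: StandardConstants
) -> list[Violation]:
    out: list[Violation] = []

    def check(name: str, expected: object, observed: object) -> None:
        if expected != observed:
            out.append(Violation(name, expected, observed))

    level_names = {1: "level_1", 2: "level_2", 3: "level_3", 4: "level_4"}
    for group, expect in constants.cod_related_by_group.items():
        total = 0
        for level, key in level_names.items():
            n = registry.group_level_count(group, level)
            check(f"{group} {key}", expect[key], n)
            total += n
        check(f"{group} cod_related total", expect["total"], total)
    for level, key in level_names.items():
        check(f"distinct {key}", constants.distinct_by_level[key],
              registry.distinct_count(level))
    check("distinct cod_related total", constants.distinct_by_level["total"],
          registry.distinct_count())
    for category, expected in constants.non_cod_by_group.items():
        for group in AGE_GROUPS:
            check(f"{group} {category}",
                  expected, len(registry.for_age_group(group, category)))
    for group, expected in constants.group_totals.items():
        check(f"{group} total incl. non-CoD", expected,
              len(registry.for_age_group(group)))
    return out


def registry_consistency_report(
    registry: IndicatorRegistry,
    cause_list: CauseList,
    constants: StandardConstants,
    subsumption: Optional[Iterable[SubsumptionEntry]] = None,
) -> list[Violation]:
    """Check every printed-count invariant; empty list iff all hold."""
    out = _registry_count_violations(registry, constants)

    def check(name: str, expected: object, observed: object) -> None:
        if expected != observed:
            out.append(Violation(name, expected, observed))

    check("leaf cause categories", constants.n_causes_2012, len(cause_list))
    check("retained + new = 2012 indicators",
          constants.n_indicators_2012, constants.n_retained + constants.n_new)
    check("2007 indicators - excluded = retained",
          constants.n_retained, constants.n_indicators_2007 - constants.n_excluded)
    level_sum = sum(
        constants.distinct_by_level[k]
        for k in ("level_1", "level_2", "level_3", "level_4")
    )
    check("sum of distinct per-level counts", constants.distinct_by_level["total"],
          level_sum)
    if subsumption is not None:
        entries = list(subsumption)
        check("subsumption entries", constants.n_subsumed, len(entries))
        leaf_titles = {c.title for c in cause_list.leaf_categories()}
        for entry in entries:
            if entry.target_va_code not in cause_list:
                out.append(Violation("subsumption target",
                                     "resolvable", entry.target_va_code))
            if entry.cause_2007 in leaf_titles:
                out.append(Violation("subsumption source",
                                     "absent from 2012 list", entry.cause_2007))
    return out
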