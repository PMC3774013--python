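"""ICD-10 code algebra and bidirectional mapping onto the VA cause list.

The mapping is precedence-resolved: when several rules cover a code, the
most specific rule wins (explicit four-character code, then single
category, then multi-category range), residual categories lose to
specific ones, and any remaining tie is broken by cause-list order.
Ties that survive all three keys (notably P95, claimed by both
stillbirth categories) are reported as ambiguous rather than silently
resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator, Optional, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .standard import CauseList

__all__ = [
    "ICDCode",
    "ICDRange",
    "MappingRule",
    "MappingResult",
    "ICDParseError",
    "parse_icd",
    "parse_range",
    "range_contains",
    "build_rules",
    "map_from_icd",
    "map_to_icd",
    "coverage_audit",
    "UnmappedReport",
    "category_universe",
]

_CODE_RE = re.compile(r"^([A-Z])([0-9]{2})(?:\.([0-9]))?$")


class ICDParseError(ValueError):
    """Raised when ICD-10 text does not parse as letter + 2 digits (+ .digit)."""


@dataclass(frozen=True, order=False)
class ICDCode:
    """A parsed ICD-10 code: chapter letter, 2-digit category, optional sub digit."""

    letter: str
    category: int
    sub: Optional[int] = None

    def __str__(self) -> str:
        base = f"{self.letter}{self.category:02d}"
        return base if self.sub is None else f"{base}.{self.sub}"

    @property
    def sort_key(self) -> tuple[str, int, int]:
        # absent sub sorts before any explicit sub digit
        return (self.letter, self.category, -1 if self.sub is None else self.sub)

    @property
    def category_key(self) -> tuple[str, int]:
        return (self.letter, self.category)

    def __lt__(self, other: "ICDCode") -> bool:
        return self.sort_key < other.sort_key

    def __le__(self, other: "ICDCode") -> bool:
        return self.sort_key <= other.sort_key


def parse_icd(text: str) -> ICDCode:
    """Parse ICD-10 text such as ``"B20"`` or ``"O75.3"`` into an :class:`ICDCode`.

    Canonicalizes case and zero-padding; idempotent on canonical text.
    """
    cleaned = str(text).strip().upper()
    # tolerate un-padded single-digit categories ("B5" -> "B05")
    m = re.match(r"^([A-Z])([0-9]{1,2})(?:\.([0-9]))?$", cleaned)
    if not m:
        raise ICDParseError(f"not a valid ICD-10 code: {text!r}")
    letter, cat, sub = m.group(1), int(m.group(2)), m.group(3)
    return ICDCode(letter, cat, None if sub is None else int(sub))


@dataclass(frozen=True)
class ICDRange:
    """Inclusive interval of category-level ICD-10 codes; may span letters."""

    lo: ICDCode
    hi: ICDCode

    def __post_init__(self) -> None:
        if (self.lo.sub is not None or self.hi.sub is not None) and self.lo != self.hi:
            # a degenerate range may carry an explicit subcode (e.g. O75.3)
            raise ValueError(f"non-degenerate range endpoints must be category-level: {self}")
        if self.hi.category_key < self.lo.category_key:
            raise ValueError(f"range lower bound exceeds upper bound: {self}")

    def __str__(self) -> str:
        if self.lo == self.hi:
            return str(self.lo)
        return f"{self.lo}-{self.hi}"

    def contains(self, code: ICDCode) -> bool:
        """True iff the code's category lies in [lo, hi]; subcoded members
        belong to the range that contains their 3-character category.
        A degenerate subcoded range contains only its exact code."""
        if self.lo == self.hi and self.lo.sub is not None:
            return code == self.lo
        return self.lo.category_key <= code.category_key <= self.hi.category_key

    @property
    def n_categories(self) -> int:
        return (
            (ord(self.hi.letter) - ord(self.lo.letter)) * 100
            + self.hi.category
            - self.lo.category
            + 1
        )

    def categories(self) -> Iterator[ICDCode]:
        """Enumerate every category-level code in the range."""
        letter, cat = self.lo.letter, self.lo.category
        while (letter, cat) <= self.hi.category_key:
            yield ICDCode(letter, cat)
            cat += 1
            if cat > 99:
                cat = 0
                letter = chr(ord(letter) + 1)


def parse_range(text: str) -> ICDRange:
    """Parse range text such as ``"A00-A09"`` (en-dash tolerated) or a single code."""
    cleaned = str(text).strip().upper().replace("–", "-")
    if "-" in cleaned:
        lo_txt, hi_txt = cleaned.split("-", 1)
        lo, hi = parse_icd(lo_txt), parse_icd(hi_txt)
    else:
        lo = hi = parse_icd(cleaned)
    return ICDRange(lo, hi)


def range_contains(rng: ICDRange, code: ICDCode) -> bool:
    return rng.contains(code)


@dataclass(frozen=True)
class MappingRule:
    """One semicolon-separated "from ICD" entry of the cause table.

    Either an explicit (possibly sub-coded) code, or a category range.
    Specificity orders explicit subcode < single category < wider range.
    """

    va_code: str
    residual: bool
    table_index: int
    explicit: Optional[ICDCode] = None
    range: Optional[ICDRange] = None

    def matches(self, code: ICDCode) -> bool:
        if self.explicit is not None:
            return code == self.explicit
        assert self.range is not None
        return self.range.contains(code)

    @property
    def specificity(self) -> int:
        """Smaller is more specific; explicit subcodes rank below any category."""
        if self.explicit is not None:
            return 0
        assert self.range is not None
        return self.range.n_categories

    def __str__(self) -> str:
        body = str(self.explicit) if self.explicit is not None else str(self.range)
        return f"{body}->{self.va_code}"


@dataclass
class MappingResult:
    """Outcome of mapping one ICD code onto the VA cause list."""

    code: ICDCode
    va_codes: list[str] = field(default_factory=list)
    rule_used: Optional[MappingRule] = None
    ambiguous: bool = False

    @property
    def unmapped(self) -> bool:
        return not self.va_codes

    @property
    def va_code(self) -> Optional[str]:
        return self.va_codes[0] if self.va_codes else None


def build_rules(cause_list: "CauseList") -> list[MappingRule]:
    """Flatten the cause list's from-ICD column into an ordered rule list."""
    rules: list[MappingRule] = []
    idx = 0
    for cause in cause_list.all_categories():
        for entry in cause.from_icd:
            if entry.lo == entry.hi and entry.lo.sub is not None:
                rule = MappingRule(
                    cause.va_code, cause.residual, idx, explicit=entry.lo
                )
            else:
                rule = MappingRule(cause.va_code, cause.residual, idx, range=entry)
            rules.append(rule)
            idx += 1
    return rules


def _matching_rules(code: ICDCode, rules: Sequence[MappingRule]) -> list[MappingRule]:
    return [r for r in rules if r.matches(code)]


def map_from_icd(code: ICDCode | str, cause_list: "CauseList") -> MappingResult:
    """Map an ICD-10 code to VA cause categories under precedence resolution.

    Deterministic: among matching rules the winner minimises
    (specificity, residual, table order).  Rules tied on the first two
    keys with distinct targets yield an ambiguous result listing every
    tied target in table order (P95 -> both stillbirth categories).
    Codes matching no rule return an unmapped result, which is distinct
    from VA-99 (an explicit rule for R99).
    """
    if isinstance(code, str):
        code = parse_icd(code)
    matches = _matching_rules(code, cause_list.rules)
    if not matches:
        return MappingResult(code=code)
    matches.sort(key=lambda r: (r.specificity, r.residual, r.table_index))
    best = matches[0]
    tied = [
        r
        for r in matches
        if (r.specificity, r.residual) == (best.specificity, best.residual)
    ]
    seen: list[str] = []
    for r in tied:
        if r.va_code not in seen:
            seen.append(r.va_code)
    return MappingResult(
        code=code, va_codes=seen, rule_used=best, ambiguous=len(seen) > 1
    )


def map_to_icd(
    va_code: str, cause_list: "CauseList", context: str = "default"
) -> ICDCode:
    """Return the printed certification code for (va_code, context).

    ``default`` returns the first printed code; a named context must be
    defined for the cause or a ``KeyError`` listing valid contexts is raised.
    """
    cause = cause_list[va_code]
    if not cause.to_icd:
        raise KeyError(f"{va_code} has no certification codes")
    if context == "default":
        return cause.to_icd[0].code
    for entry in cause.to_icd:
        if entry.context == context:
            return entry.code
    valid = ["default"] + [e.context for e in cause.to_icd if e.context]
    raise KeyError(
        f"context {context!r} not defined for {va_code}; valid contexts: {valid}"
    )


def category_universe(spec: str = "A00-Y98") -> list[ICDCode]:
    """All category-level codes of the given inclusive span."""
    return list(parse_range(spec).categories())


@dataclass
class UnmappedReport:
    """Coverage audit outcome over a code universe."""

    universe: str
    unmapped: list[ICDCode]
    conflicts: list[tuple[ICDCode, list[str]]]

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)


def coverage_audit(cause_list: "CauseList", universe: str = "A00-Y98") -> UnmappedReport:
    """Scan a category-level universe for codes with no rule and for codes
    claimed by more than one non-residual rule of equal best specificity."""
    unmapped: list[ICDCode] = []
    conflicts: list[tuple[ICDCode, list[str]]] = []
    for code in category_universe(universe):
        result = map_from_icd(code, cause_list)
        if result.unmapped:
            unmapped.append(code)
        elif result.ambiguous and not result.rule_used.residual:
            conflicts.append((code, result.va_codes))
    return UnmappedReport(universe=universe, unmapped=unmapped, conflicts=conflicts)
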