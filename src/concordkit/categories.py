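"""Race/ethnicity category system and harmonization of raw source codings.

The category system is the 1997 OMB standard used by U.S. federal statistics:
Hispanic or Latino (of any race), and the non-Hispanic single-race categories
White, Black, AIAN (American Indian and Alaska Native), Asian, NHPI (Native
Hawaiian and Other Pacific Islander), plus Multiracial for two or more
selected races.  ``Unreported`` is the nonreporting state (blank, unknown,
or declined) — it is a display row, never a member of a race set.

Two harmonizers are provided: :func:`harmonize_ehr` maps free-ish EHR
ethnicity/race strings through a configurable mapping table, and
:func:`harmonize_census` maps the census-style (Hispanic flag, race set)
representation.  Hispanic ethnicity dominates any race selection in both.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Collection, Iterable, Mapping

import pandas as pd

__all__ = [
    "Category",
    "REPORTED_CATEGORIES",
    "SINGLE_RACES",
    "HarmonizedLabel",
    "RawEhrDemographic",
    "CodeMapping",
    "CodingError",
    "InvalidObservationError",
    "default_ehr_mapping",
    "harmonize_ehr",
    "harmonize_census",
    "harmonize_ehr_table",
    "parse_label_token",
]


class Category(str, Enum):
    """The seven reported OMB categories plus the nonreporting state."""

    HISPANIC = "Hispanic"
    WHITE = "White"
    BLACK = "Black"
    AIAN = "AIAN"
    ASIAN = "Asian"
    NHPI = "NHPI"
    MULTIRACIAL = "Multiracial"
    UNREPORTED = "Unreported"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed display/reporting order (matches the figure/table conventions).
REPORTED_CATEGORIES: tuple[Category, ...] = (
    Category.HISPANIC,
    Category.WHITE,
    Category.BLACK,
    Category.AIAN,
    Category.ASIAN,
    Category.NHPI,
    Category.MULTIRACIAL,
)

#: Non-Hispanic single-race categories, the only legal race-set members.
SINGLE_RACES: tuple[Category, ...] = (
    Category.WHITE,
    Category.BLACK,
    Category.AIAN,
    Category.ASIAN,
    Category.NHPI,
)

_CATEGORY_ORDER = {c: i for i, c in enumerate(REPORTED_CATEGORIES)}


class CodingError(ValueError):
    """A source code could not be mapped (strict mode) or is malformed."""


class InvalidObservationError(ValueError):
    """A census-style observation carries neither a Hispanic flag nor races."""


@dataclass(frozen=True)
class HarmonizedLabel:
    """A harmonized race/ethnicity label.

    ``race_set`` holds the underlying single-race selections of a Multiracial
    response when they are observed (always, for census responses).  EHR
    dialects may carry a bare "multiracial" code with unknown components, in
    which case the set is empty.  Hispanic and Unreported never carry races.
    """

    category: Category
    race_set: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        races = frozenset(self.race_set)
        object.__setattr__(self, "race_set", races)
        if any(r not in SINGLE_RACES for r in races):
            raise ValueError("race_set may contain only single-race categories")
        if self.category is Category.MULTIRACIAL:
            if len(races) == 1:
                raise ValueError("Multiracial race_set must have 0 (unknown) or >= 2 members")
        elif races:
            raise ValueError(f"race_set must be empty for category {self.category.value}")

    @property
    def token(self) -> str:
        """Canonical string form, e.g. ``White`` or ``Multiracial[Black+White]``."""
        if self.category is Category.MULTIRACIAL and self.race_set:
            inner = "+".join(
                c.value for c in sorted(self.race_set, key=_CATEGORY_ORDER.__getitem__)
            )
            return f"Multiracial[{inner}]"
        return self.category.value

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"HarmonizedLabel({self.token})"


def parse_label_token(token: str) -> HarmonizedLabel:
    """Inverse of :attr:`HarmonizedLabel.token`."""
    token = token.strip()
    if token.startswith("Multiracial[") and token.endswith("]"):
        inner = token[len("Multiracial[") : -1]
        races = frozenset(Category(part) for part in inner.split("+") if part)
        return HarmonizedLabel(Category.MULTIRACIAL, races)
    return HarmonizedLabel(Category(token))


@dataclass(frozen=True)
class RawEhrDemographic:
    """Raw EHR demographic coding: an ethnicity string and 0+ race strings.

    Either field may be blank/unknown — that missingness is itself the
    phenomenon under study, not an error.
    """

    ethnicity_code: str = ""
    race_codes: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "race_codes", tuple(self.race_codes))


#: Sentinel mapping value for ethnicity strings meaning "not Hispanic".
NOT_HISPANIC = "NotHispanic"

_VALID_TARGETS = {c.value for c in Category} | {NOT_HISPANIC}


class CodeMapping:
    """Source-code → category mapping table (case-insensitive, trimmed).

    The table is two-column delimited text with a header ``source_code,category``.
    ``category`` is one of the eight category names or the special value
    ``NotHispanic`` for ethnicity strings that merely negate Hispanic origin.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._map: dict[str, str] = {}
        for code, target in entries.items():
            if target not in _VALID_TARGETS:
                raise CodingError(f"unknown mapping target {target!r} for code {code!r}")
            self._map[_norm(code)] = target

    @classmethod
    def from_csv(cls, path: str | Path) -> "CodeMapping":
        entries: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or {"source_code", "category"} - set(reader.fieldnames):
                raise CodingError(f"mapping table {path} must have columns source_code,category")
            for row in reader:
                entries[row["source_code"]] = row["category"].strip()
        return cls(entries)

    def lookup(self, code: str) -> str | None:
        return self._map.get(_norm(code))

    def __len__(self) -> int:
        return len(self._map)


def _norm(code: str) -> str:
    return str(code).strip().lower()


_DEFAULT_MAPPING_PATH = Path(__file__).parent / "data" / "ehr_race_mapping.csv"
_default_mapping_cache: CodeMapping | None = None


def default_ehr_mapping() -> CodeMapping:
    """The documented default fixture mapping common EHR strings to categories."""
    global _default_mapping_cache
    if _default_mapping_cache is None:
        _default_mapping_cache = CodeMapping.from_csv(_DEFAULT_MAPPING_PATH)
    return _default_mapping_cache


def harmonize_ehr(
    raw: RawEhrDemographic,
    mapping: CodeMapping | None = None,
    *,
    strict: bool = False,
    unmapped_log: dict | None = None,
) -> HarmonizedLabel:
    """Harmonize a raw EHR demographic record to an OMB category.

    Hispanic ethnicity dominates any race entry; multiple distinct mapped
    races yield Multiracial with the race set retained; unknown, declined and
    absent codes all collapse to Unreported.  In strict mode an unmapped code
    raises :class:`CodingError` naming the code; otherwise it maps to
    Unreported and is tallied in ``unmapped_log``.
    """
    mapping = mapping or default_ehr_mapping()

    def _miss(code: str) -> None:
        if strict:
            raise CodingError(f"unmapped EHR source code: {code!r}")
        if unmapped_log is not None:
            unmapped_log[code] = unmapped_log.get(code, 0) + 1

    race_candidates: list[str] = [c for c in raw.race_codes if _norm(c)]
    eth = _norm(raw.ethnicity_code)
    if eth:
        target = mapping.lookup(eth)
        if target is None:
            _miss(raw.ethnicity_code)
        elif target == Category.HISPANIC.value:
            return HarmonizedLabel(Category.HISPANIC)
        elif target not in (NOT_HISPANIC, Category.UNREPORTED.value):
            # some EHR dialects cram a race string into the ethnicity field
            race_candidates.append(raw.ethnicity_code)

    races: set[Category] = set()
    direct_multiracial = False
    for code in race_candidates:
        target = mapping.lookup(code)
        if target is None:
            _miss(code)
            continue
        cat = Category(target) if target != NOT_HISPANIC else None
        if cat is Category.HISPANIC:
            return HarmonizedLabel(Category.HISPANIC)
        if cat is Category.MULTIRACIAL:
            direct_multiracial = True
        elif cat in SINGLE_RACES:
            races.add(cat)

    if len(races) >= 2:
        return HarmonizedLabel(Category.MULTIRACIAL, frozenset(races))
    if direct_multiracial:
        return HarmonizedLabel(Category.MULTIRACIAL)  # components unknown
    if len(races) == 1:
        return HarmonizedLabel(next(iter(races)))
    return HarmonizedLabel(Category.UNREPORTED)


def harmonize_census(hispanic: bool, races: Collection[Category]) -> HarmonizedLabel:
    """Harmonize a census-style (Hispanic flag, race set) response.

    Hispanic precedence: ``hispanic=True`` yields Hispanic regardless of
    races.  Otherwise a single race yields that category and two or more
    yield Multiracial with the race set retained.
    """
    if hispanic:
        return HarmonizedLabel(Category.HISPANIC)
    races = frozenset(Category(r) for r in races)
    if not races:
        raise InvalidObservationError(
            "observation has hispanic=False and an empty race set"
        )
    if len(races) == 1:
        return HarmonizedLabel(next(iter(races)))
    return HarmonizedLabel(Category.MULTIRACIAL, races)


def harmonize_ehr_table(
    ehr: pd.DataFrame,
    mapping: CodeMapping | None = None,
    *,
    strict: bool = False,
    unmapped_log: dict | None = None,
    race_sep: str = ";",
) -> pd.DataFrame:
    """Vectorized harmonization of an EHR table.

    ``ehr`` needs columns ``person_key``, ``ethnicity_code``, ``race_codes``
    (``race_sep``-joined strings).  Unique (ethnicity, races) combinations are
    harmonized once through :func:`harmonize_ehr` and joined back, so the cost
    scales with the coding vocabulary rather than the cohort size.

    Returns a frame with ``person_key``, ``ehr_category``, ``ehr_races``
    (label token) plus any passthrough columns (e.g. ``practice_key``).
    """
    mapping = mapping or default_ehr_mapping()
    eth = ehr["ethnicity_code"].fillna("").astype(str)
    rac = ehr["race_codes"].fillna("").astype(str)
    combo = eth + "\x1f" + rac
    tokens = {}
    for key in combo.unique():
        e, r = key.split("\x1f", 1)
        raw = RawEhrDemographic(e, tuple(p for p in r.split(race_sep) if p.strip()))
        tokens[key] = harmonize_ehr(
            raw, mapping, strict=strict, unmapped_log=unmapped_log
        ).token
    out = ehr.drop(columns=["ethnicity_code", "race_codes"]).copy()
    token = combo.map(tokens)
    out["ehr_category"] = token.str.replace(r"\[.*\]$", "", regex=True)
    out["ehr_races"] = token
    return out
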