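"""Reduce a person's multiple census-style observations to one label.

A person may appear in several census/survey responses (decennial census
2000/2010/2020 and annual ACS-style microdata).  The resolution protocol is:

1. drop observations whose response was *allocated* (imputed by survey
   processing rather than reported);
2. for each (source, year), if the harmonized labels of that person's
   observations disagree, drop the whole (source, year) group (a signature of
   record-linkage error); identical duplicates collapse to one;
3. among survivors, prefer the decennial census over the ACS-style source
   (configurable), and the most recent year within the chosen source.

Absence of a surviving observation is a valid outcome — such persons have no
census label and fall out of the linked cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .categories import (
    Category,
    HarmonizedLabel,
    InvalidObservationError,
    harmonize_census,
    parse_label_token,
)

__all__ = [
    "Source",
    "CensusObservation",
    "ResolutionResult",
    "Window",
    "ConfigurationError",
    "filter_allocated",
    "drop_source_year_conflicts",
    "resolve",
    "resolve_table",
    "pairwise_census_labels",
    "parse_race_field",
]


class Source(str, Enum):
    DECENNIAL = "DECENNIAL"
    ACS = "ACS"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


#: Resolution priority: lower sorts first.
_SOURCE_PRIORITY = {Source.DECENNIAL: 0, Source.ACS: 1}


class ConfigurationError(ValueError):
    """Invalid resolution configuration (e.g. overlapping pair windows)."""


def parse_race_field(races: str, sep: str = ";") -> frozenset:
    """Parse a delimited race field like ``"White;AIAN"`` into categories."""
    out = set()
    for part in str(races).split(sep):
        part = part.strip()
        if part:
            out.add(Category(part))
    return frozenset(out)


@dataclass(frozen=True)
class CensusObservation:
    """One survey response for a person."""

    person_key: str
    source: Source
    year: int
    allocated: bool
    hispanic: bool
    races: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", Source(self.source))
        object.__setattr__(
            self, "races", frozenset(Category(r) for r in self.races)
        )
        if not (1999 < self.year < 2100):
            raise ValueError(f"implausible census year {self.year}")

    def label(self) -> HarmonizedLabel:
        return harmonize_census(self.hispanic, self.races)


@dataclass(frozen=True)
class ResolutionResult:
    person_key: str
    label: HarmonizedLabel | None
    provenance: tuple | None  # (Source, year) of the chosen observation
    n_dropped_allocated: int = 0
    n_dropped_conflict: int = 0


def filter_allocated(observations: Sequence[CensusObservation]) -> list:
    """Keep only observations with ``allocated == False``, order preserved."""
    return [o for o in observations if not o.allocated]


def drop_source_year_conflicts(
    observations: Sequence[CensusObservation],
) -> list:
    """Drop every (source, year) group with non-identical harmonized labels.

    Groups whose labels all agree are deduplicated to one representative
    (the first in input order).  All observations must belong to one person.
    """
    groups: dict[tuple, list[CensusObservation]] = {}
    order: list[tuple] = []
    for obs in observations:
        key = (obs.source, obs.year)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(obs)
    kept: list[CensusObservation] = []
    for key in order:
        members = groups[key]
        labels = {m.label().token for m in members}
        if len(labels) == 1:
            kept.append(members[0])
    return kept


def resolve(
    observations: Sequence[CensusObservation],
    *,
    decennial_priority: bool = True,
) -> ResolutionResult:
    """Resolve one person's observations to a single prioritized label.

    With ``decennial_priority`` (default), any surviving decennial response
    beats any ACS-style response even if the latter is more recent; recency
    then decides within the chosen source.  Setting it to False switches to
    global recency with source priority only as a tie-break.
    """
    observations = list(observations)
    persons = {o.person_key for o in observations}
    if len(persons) > 1:
        raise ValueError("resolve() expects observations of a single person")
    person = next(iter(persons)) if persons else ""

    non_alloc = filter_allocated(observations)
    n_alloc = len(observations) - len(non_alloc)
    survivors = drop_source_year_conflicts(non_alloc)
    # conflict counter tallies rows removed by the conflict rule (dedup of
    # identical rows is not a drop in the accounting sense)
    kept_keys = {(o.source, o.year) for o in survivors}
    n_conflict = sum(1 for o in non_alloc if (o.source, o.year) not in kept_keys)

    if not survivors:
        return ResolutionResult(person, None, None, n_alloc, n_conflict)

    if decennial_priority:
        best = min(survivors, key=lambda o: (_SOURCE_PRIORITY[o.source], -o.year))
    else:
        best = min(survivors, key=lambda o: (-o.year, _SOURCE_PRIORITY[o.source]))
    return ResolutionResult(
        person, best.label(), (best.source, best.year), n_alloc, n_conflict
    )


# ---------------------------------------------------------------------------
# table-level (vectorized) resolution
# ---------------------------------------------------------------------------

def _label_tokens(census: pd.DataFrame) -> pd.Series:
    """Harmonized label token per observation row (vectorized via uniques)."""
    hisp = census["hispanic"].astype(bool)
    races = census["races"].fillna("").astype(str)
    token_of: dict[str, str | None] = {}
    for r in races[~hisp].unique():
        rs = parse_race_field(r)
        if not rs:
            token_of[r] = None  # invalid: neither hispanic nor any race
        else:
            token_of[r] = harmonize_census(False, rs).token
    tokens = races.map(token_of)
    tokens[hisp] = Category.HISPANIC.value
    return tokens


def resolve_table(
    census: pd.DataFrame,
    *,
    decennial_priority: bool = True,
) -> pd.DataFrame:
    """Vectorized :func:`resolve` over a full census observation table.

    ``census`` needs columns ``person_key``, ``source`` (``DECENNIAL``/``ACS``),
    ``year``, ``allocated`` (0/1), ``hispanic`` (0/1), ``races``
    (semicolon-joined single-race names).  Returns one row per person with
    ``census_category``, ``census_races`` (token; NaN when no observation
    survived), provenance columns and drop counters.  Agrees row-for-row with
    the scalar :func:`resolve`.
    """
    df = census.copy()
    df["_token"] = _label_tokens(df)
    invalid = df["_token"].isna() & ~df["hispanic"].astype(bool)
    df = df[~invalid]

    all_persons = pd.Index(census["person_key"].unique(), name="person_key")

    alloc = df["allocated"].astype(bool)
    n_alloc = (
        df.loc[alloc].groupby("person_key").size().reindex(all_persons, fill_value=0)
    )
    df = df[~alloc]

    gkey = ["person_key", "source", "year"]
    nuniq = df.groupby(gkey)["_token"].transform("nunique")
    conflict = nuniq > 1
    n_conflict = (
        df.loc[conflict]
        .groupby("person_key")
        .size()
        .reindex(all_persons, fill_value=0)
    )
    df = df[~conflict].drop_duplicates(subset=gkey + ["_token"])

    prio = df["source"].map(
        {s.value: p for s, p in _SOURCE_PRIORITY.items()}
    )
    if decennial_priority:
        df = df.assign(_prio=prio).sort_values(
            ["person_key", "_prio", "year"], ascending=[True, True, False]
        )
    else:
        df = df.assign(_prio=prio).sort_values(
            ["person_key", "year", "_prio"], ascending=[True, False, True]
        )
    best = df.drop_duplicates(subset="person_key", keep="first")

    out = pd.DataFrame(index=all_persons)
    best = best.set_index("person_key")
    out["census_races"] = best["_token"]
    out["census_category"] = out["census_races"].str.replace(
        r"\[.*\]$", "", regex=True
    )
    out["provenance_source"] = best["source"]
    out["provenance_year"] = best["year"]
    out["n_dropped_allocated"] = n_alloc
    out["n_dropped_conflict"] = n_conflict
    return out.reset_index()


@dataclass(frozen=True)
class Window:
    """A source/year window, e.g. ``Window(Source.ACS, 2019, 2022)``."""

    source: Source
    year_min: int
    year_max: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", Source(self.source))
        if self.year_max is None:
            object.__setattr__(self, "year_max", self.year_min)
        if self.year_max < self.year_min:
            raise ConfigurationError("window year_max < year_min")

    def overlaps(self, other: "Window") -> bool:
        return (
            self.source == other.source
            and self.year_min <= other.year_max
            and other.year_min <= self.year_max
        )

    def mask(self, census: pd.DataFrame) -> pd.Series:
        return (
            (census["source"] == self.source.value)
            & (census["year"] >= self.year_min)
            & (census["year"] <= self.year_max)
        )


def pairwise_census_labels(
    census: pd.DataFrame,
    window_a: Window,
    window_b: Window,
) -> pd.DataFrame:
    """Resolved label within each of two disjoint windows, for persons in both.

    Used for intra-census discordance analyses, e.g. ACS 2019–2022 vs the 2020
    decennial response, or responses to two decennial years.  The same
    allocation and conflict filtering applies within each window.
    """
    if window_a.overlaps(window_b):
        raise ConfigurationError(f"pair windows overlap: {window_a} / {window_b}")
    res_a = resolve_table(census[window_a.mask(census)])
    res_b = resolve_table(census[window_b.mask(census)])
    a = res_a.dropna(subset=["census_races"]).set_index("person_key")
    b = res_b.dropna(subset=["census_races"]).set_index("person_key")
    both = a.index.intersection(b.index)
    return pd.DataFrame(
        {
            "person_key": both,
            "category_a": a.loc[both, "census_category"].values,
            "races_a": a.loc[both, "census_races"].values,
            "category_b": b.loc[both, "census_category"].values,
            "races_b": b.loc[both, "census_races"].values,
        }
    )
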