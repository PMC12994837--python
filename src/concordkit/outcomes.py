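"""Clinical outcome coding: collapse to 3-digit ICD-10 groups, ever-indicators.

Clinical events arrive as ICD-9, ICD-10 or SNOMED CT codes.  ICD-9 and
SNOMED codes are first crosswalked to an ICD-10 equivalent (via a shipped
fixture table covering the common primary-care groups; the full national
GEM/SNOMED maps are external reference data), then every ICD-10 code is
collapsed to its first three characters — the letter + two digits stem that
names the general condition (E11 for Type 2 diabetes, I10 for essential
hypertension, ...).  Per patient we keep only the *ever* indicator for each
stem: 1 if any mapped event exists, over the whole record window.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CodingError

__all__ = [
    "System",
    "Crosswalk",
    "default_crosswalk",
    "to_icd10_group",
    "ever_indicators",
    "top_k_outcomes",
    "UNMAPPED",
]

ICD10_STEM_RE = re.compile(r"^[A-Z][0-9]{2}$")

#: Sentinel returned for codes the crosswalk cannot map.
UNMAPPED = None

VALID_SYSTEMS = ("ICD9", "ICD10", "SNOMED")


class Crosswalk:
    """(source code, system) → ICD-10 code mapping table."""

    def __init__(self, entries: Mapping[tuple, str]):
        self._map = {
            (str(code).strip().upper(), system): icd10
            for (code, system), icd10 in entries.items()
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "Crosswalk":
        entries: dict[tuple, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            need = {"source_code", "system", "icd10_code"}
            if reader.fieldnames is None or need - set(reader.fieldnames):
                raise CodingError(f"crosswalk {path} must have columns {sorted(need)}")
            for row in reader:
                sys_ = row["system"].strip().upper()
                if sys_ not in ("ICD9", "SNOMED"):
                    raise CodingError(f"crosswalk system must be ICD9/SNOMED, got {sys_}")
                entries[(row["source_code"], sys_)] = row["icd10_code"].strip()
        return cls(entries)

    def lookup(self, code: str, system: str) -> str | None:
        return self._map.get((str(code).strip().upper(), system))

    def __len__(self) -> int:
        return len(self._map)


_DEFAULT_CROSSWALK_PATH = Path(__file__).parent / "data" / "icd_crosswalk.csv"
_default_crosswalk_cache: Crosswalk | None = None


def default_crosswalk() -> Crosswalk:
    """Fixture crosswalk shipped with the package (common ICD-9/SNOMED codes)."""
    global _default_crosswalk_cache
    if _default_crosswalk_cache is None:
        _default_crosswalk_cache = Crosswalk.from_csv(_DEFAULT_CROSSWALK_PATH)
    return _default_crosswalk_cache


def _truncate(icd10: str) -> str:
    stem = icd10.strip().upper().replace(".", "")[:3]
    if not ICD10_STEM_RE.match(stem):
        raise CodingError(f"malformed ICD-10 code {icd10!r} (stem {stem!r})")
    return stem


def to_icd10_group(
    code: str, system: str, crosswalk: Crosswalk | None = None
) -> str | None:
    """Map one clinical code to its 3-character ICD-10 group.

    ICD-10 codes are truncated directly (``E11.42`` → ``E11``); ICD-9 and
    SNOMED codes go through the crosswalk first.  Unknown ICD-9/SNOMED codes
    return :data:`UNMAPPED`; a malformed ICD-10 stem raises
    :class:`~concordkit.categories.CodingError`.
    """
    system = str(system).strip().upper()
    if system not in VALID_SYSTEMS:
        raise CodingError(f"unknown coding system {system!r}")
    if system == "ICD10":
        return _truncate(code)
    crosswalk = crosswalk or default_crosswalk()
    icd10 = crosswalk.lookup(code, system)
    if icd10 is None:
        return UNMAPPED
    return _truncate(icd10)


def ever_indicators(
    events: pd.DataFrame,
    crosswalk: Crosswalk | None = None,
    persons: Iterable | None = None,
    *,
    unmapped_log: dict | None = None,
) -> pd.DataFrame:
    """Person x outcome-group binary matrix from a long event table.

    ``events`` needs columns ``person_key``, ``code``, ``system``.  Duplicate
    and repeated events collapse to a single 1.  ``persons`` optionally fixes
    the row index (cohort members without events get all-zero rows).
    Unmapped codes are dropped and tallied in ``unmapped_log``; malformed
    ICD-10 codes in the table are treated the same way (logged, dropped)
    since real extracts contain junk.
    """
    crosswalk = crosswalk or default_crosswalk()
    pairs = events[["code", "system"]].astype(str)
    combo = pairs["code"] + "\x1f" + pairs["system"].str.upper()
    group_of: dict[str, str | None] = {}
    for key in combo.unique():
        code, system = key.split("\x1f")
        try:
            group_of[key] = to_icd10_group(code, system, crosswalk)
        except CodingError:
            group_of[key] = UNMAPPED
    groups = combo.map(group_of)
    dropped = groups.isna()
    if unmapped_log is not None and dropped.any():
        for key, n in combo[dropped].value_counts().items():
            code = key.split("\x1f")[0]
            unmapped_log[code] = unmapped_log.get(code, 0) + int(n)
    ok = events.loc[~dropped, ["person_key"]].assign(outcome_group=groups[~dropped])
    mat = (
        ok.drop_duplicates()
        .assign(flag=1)
        .pivot_table(
            index="person_key", columns="outcome_group", values="flag", fill_value=0
        )
    )
    if persons is not None:
        mat = mat.reindex(pd.Index(persons, name="person_key"), fill_value=0)
    mat.columns.name = "outcome_group"
    return mat.astype(np.int8).sort_index(axis=1)


def top_k_outcomes(
    matrix: pd.DataFrame,
    k: int,
    exclude_prefixes: Sequence[str] = (),
) -> list:
    """The ``k`` most prevalent outcome groups, by descending patient count.

    ``exclude_prefixes`` removes administrative stems (e.g. ``("Z",)`` to
    drop reasons-for-encounter codes).  Ties break lexicographically.  If
    fewer than ``k`` groups remain, all are returned (a warning is implicit
    in the shorter result).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = matrix.sum(axis=0)
    if exclude_prefixes:
        keep = [
            g for g in counts.index if not any(g.startswith(p) for p in exclude_prefixes)
        ]
        counts = counts.loc[keep]
    order = sorted(counts.index, key=lambda g: (-counts[g], g))
    return order[:k]
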