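"""Per-person concordance classification and cross-tabulation summaries.

A *record* pairs one person's harmonized EHR label with their resolved census
label (the census label is required — persons with no valid census
race/ethnicity are outside the linked cohort).  Classification:

- EHR Unreported                              → NONREPORTING
- equal categories                            → CONCORDANT (Multiracial vs
  Multiracial is concordant regardless of race-set identity)
- census Multiracial whose race set contains
  the EHR single race, when allowed           → PARTIAL
- anything else                               → DISCORDANT

Record tables are plain DataFrames with columns ``person_key``,
``ehr_category``, ``ehr_races`` (label token), ``census_category``,
``census_races`` and optionally ``practice_key``; the table operations here
are vectorized over unique label pairs so they scale to millions of rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .categories import (
    Category,
    REPORTED_CATEGORIES,
    HarmonizedLabel,
    parse_label_token,
)

__all__ = [
    "Status",
    "UndefinedRateError",
    "classify",
    "classify_table",
    "CrossTab",
    "build_crosstab",
    "discordance_rate",
    "missingness_rate",
    "discordant_composition",
    "multiracial_agreement",
    "pct",
]


class Status(str, Enum):
    CONCORDANT = "CONCORDANT"
    PARTIAL = "PARTIAL"
    DISCORDANT = "DISCORDANT"
    NONREPORTING = "NONREPORTING"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested over an empty denominator."""


def pct(x: float, nd: int = 1) -> float:
    """Proportion → percent at the display precision (round-half-even)."""
    return round(100.0 * x, nd)


def classify(
    ehr_label: HarmonizedLabel,
    census_label: HarmonizedLabel,
    allow_partial: bool = False,
    *,
    mirror_partial: bool = False,
) -> Status:
    """Classify one (EHR label, census label) pair.

    Partial concordance is defined in the census-Multiracial direction: a
    single EHR race contained in the census race set.  ``mirror_partial``
    additionally honors the mirrored case (census single race contained in a
    known EHR Multiracial set); it is off by default, which matches treating
    that case as discordant.
    """
    if census_label.category is Category.UNREPORTED:
        raise ValueError("census label may not be Unreported in the linked cohort")
    if ehr_label.category is Category.UNREPORTED:
        return Status.NONREPORTING
    if ehr_label.category is census_label.category:
        return Status.CONCORDANT
    if allow_partial:
        if (
            census_label.category is Category.MULTIRACIAL
            and ehr_label.category in census_label.race_set
        ):
            return Status.PARTIAL
        if (
            mirror_partial
            and ehr_label.category is Category.MULTIRACIAL
            and census_label.category in ehr_label.race_set
        ):
            return Status.PARTIAL
    return Status.DISCORDANT


def classify_table(
    records: pd.DataFrame,
    allow_partial: bool = False,
    *,
    mirror_partial: bool = False,
) -> pd.Series:
    """Vectorized :func:`classify` over a record table (status strings).

    Scales to multi-million-row tables: both token columns are factorized and
    statuses are computed once per distinct (EHR token, census token) pair.
    """
    e_codes, e_uniq = pd.factorize(records["ehr_races"])
    c_codes, c_uniq = pd.factorize(records["census_races"])
    key = e_codes.astype(np.int64) * len(c_uniq) + c_codes
    lut = np.empty(len(e_uniq) * len(c_uniq), dtype=object)
    for k in np.unique(key):
        e, c = e_uniq[k // len(c_uniq)], c_uniq[k % len(c_uniq)]
        lut[k] = classify(
            parse_label_token(str(e)),
            parse_label_token(str(c)),
            allow_partial,
            mirror_partial=mirror_partial,
        ).value
    return pd.Series(lut[key], index=records.index, name="status")


_EHR_ROWS = [c.value for c in REPORTED_CATEGORIES] + [Category.UNREPORTED.value]
_CENSUS_COLS = [c.value for c in REPORTED_CATEGORIES]


@dataclass
class CrossTab:
    """8 x 7 person-count matrix (EHR rows incl. Unreported x census columns).

    ``row_pct`` rows sum to 100 across the seven census columns.  ``col_pct``
    normalizes the seven *reported* EHR rows within each census column to 100;
    its Unreported row is instead the percent of the full column (including
    nonreporting), mirroring the missingness presentation.
    """

    counts: pd.DataFrame

    @property
    def row_pct(self) -> pd.DataFrame:
        denom = self.counts.sum(axis=1)
        return 100.0 * self.counts.div(denom.where(denom > 0), axis=0)

    @property
    def col_pct(self) -> pd.DataFrame:
        reported = self.counts.loc[_CENSUS_COLS]
        denom_rep = reported.sum(axis=0)
        out = 100.0 * reported.div(denom_rep.where(denom_rep > 0), axis=1)
        denom_all = self.counts.sum(axis=0)
        out.loc[Category.UNREPORTED.value] = (
            100.0
            * self.counts.loc[Category.UNREPORTED.value]
            / denom_all.where(denom_all > 0)
        )
        return out

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    def to_csv(self, prefix) -> None:
        """Write the three panels (counts, row %, col %) next to ``prefix``."""
        self.counts.to_csv(f"{prefix}_counts.csv")
        self.row_pct.round(1).to_csv(f"{prefix}_row_pct.csv")
        self.col_pct.round(1).to_csv(f"{prefix}_col_pct.csv")


def build_crosstab(records: pd.DataFrame) -> CrossTab:
    """Tally persons into the EHR-category x census-category matrix."""
    counts = pd.crosstab(records["ehr_category"], records["census_category"])
    counts = counts.reindex(index=_EHR_ROWS, columns=_CENSUS_COLS, fill_value=0)
    counts.index.name = "ehr_category"
    counts.columns.name = "census_category"
    return CrossTab(counts.astype(np.int64))


def discordance_rate(records: pd.DataFrame, allow_partial: bool = False) -> float:
    """Discordant share of persons who report race/ethnicity in both sources.

    With ``allow_partial``, PARTIAL records count as non-discordant; without
    it they fold into the discordant numerator.  NONREPORTING records are
    excluded from the denominator.
    """
    status = classify_table(records, allow_partial=allow_partial)
    reporting = status != Status.NONREPORTING.value
    n = int(reporting.sum())
    if n == 0:
        raise UndefinedRateError("no reporting records")
    k = int((status == Status.DISCORDANT.value).sum())
    return k / n


def missingness_rate(records: pd.DataFrame, by: str | Category | None = None) -> float:
    """EHR nonreporting share, overall or within one census-category column."""
    if by is not None:
        by = Category(by).value
        records = records[records["census_category"] == by]
    n = len(records)
    if n == 0:
        raise UndefinedRateError(f"empty stratum {by!r}")
    k = int((records["ehr_category"] == Category.UNREPORTED.value).sum())
    return k / n


def discordant_composition(
    records: pd.DataFrame, standpoint: str = "EHR"
) -> pd.Series:
    """Per-category percent shares of the (strictly) discordant set.

    ``standpoint`` is ``"EHR"`` (shares by EHR-recorded category) or
    ``"CENSUS"`` (shares by census-recorded category).  Shares sum to 100 and
    match the cross-tab's off-diagonal row/column sums.
    """
    status = classify_table(records, allow_partial=False)
    disc = records[status == Status.DISCORDANT.value]
    if disc.empty:
        raise UndefinedRateError("no discordant records")
    col = {"EHR": "ehr_category", "CENSUS": "census_category"}[standpoint.upper()]
    counts = disc[col].value_counts().reindex(_CENSUS_COLS, fill_value=0)
    return 100.0 * counts / counts.sum()


def multiracial_agreement(records: pd.DataFrame) -> dict:
    """Agreement summary for persons Multiracial in either source.

    Restricted to both-reporting persons.  Returns the union size, the count
    recorded Multiracial in both sources, and the count/share that are fully
    discordant once partial concordance is allowed (the EHR single race
    matches none of the census race selections).
    """
    status_strict = classify_table(records, allow_partial=False)
    reporting = records[status_strict != Status.NONREPORTING.value]
    multi = Category.MULTIRACIAL.value
    either = reporting[
        (reporting["ehr_category"] == multi)
        | (reporting["census_category"] == multi)
    ]
    if either.empty:
        raise UndefinedRateError("no Multiracial records in either source")
    both = (either["ehr_category"] == multi) & (either["census_category"] == multi)
    status_partial = classify_table(either, allow_partial=True)
    fully_disc = status_partial == Status.DISCORDANT.value
    return {
        "n_either": int(len(either)),
        "n_both": int(both.sum()),
        "pct_both": pct(both.mean()),
        "n_fully_discordant": int(fully_disc.sum()),
        "pct_fully_discordant": pct(fully_disc.mean()),
    }
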