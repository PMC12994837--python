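"""Demographic contrasts across concordance groups and practice-level models.

Cohort contrasts: patients are split into concordant / discordant /
nonreporting groups (strict classification) and compared on 13
characteristic levels — three age bands, two sex categories, four social
vulnerability (SVI) quartile tiers and four rurality (RUCA) tiers — with a
continuity-corrected two-sample proportion z-test for each of the 3 group
pairs, 39 comparisons in all, at a Bonferroni-adjusted level.  Band
percentages use the full group size as denominator; persons missing an
address-derived covariate simply appear in no band row (so SVI/RUCA rows do
not total 100%).

Practice-level analyses summarize each practice (size, discordance rate,
missingness rate, non-White share under the census labeling), fit simple
linear regressions across practices, and report concentration of specific
discordance patterns in the largest contributing practices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .categories import Category, SINGLE_RACES
from .concordance import Status, UndefinedRateError, classify_table

__all__ = [
    "band_covariates",
    "two_proportion_test",
    "demographic_contrasts",
    "practice_summaries",
    "practice_regressions",
    "concentration_report",
    "zero_multiracial_practices",
    "DEFAULT_MODELS",
    "LEVELS",
]

AGE_BANDS = ("<18", "18-64", ">=65")
SEX_BANDS = ("male", "female")
SVI_BANDS = ("[0,25]", "(25,50]", "(50,75]", "(75,100]")
RUCA_BANDS = ("metropolitan", "micropolitan", "small town", "rural")

#: The 13 characteristic levels compared across group pairs (3+2+4+4).
LEVELS: tuple[tuple, ...] = tuple(
    [("age_band", b) for b in AGE_BANDS]
    + [("sex_band", b) for b in SEX_BANDS]
    + [("svi_band", b) for b in SVI_BANDS]
    + [("ruca_band", b) for b in RUCA_BANDS]
)

GROUP_PAIRS = (
    ("concordant", "discordant"),
    ("concordant", "nonreporting"),
    ("discordant", "nonreporting"),
)


def band_covariates(
    covariates: pd.DataFrame,
    reference_date: str = "2021-12-31",
) -> pd.DataFrame:
    """Band raw covariates into the reporting tiers.

    ``covariates`` needs ``person_key``, ``dob``, ``sex``, ``svi_score``
    (0–100 percentile, NaN if no address), ``ruca_code`` (1–10, NaN if no
    address).  Age is computed at ``reference_date`` (default: end of the
    study window analog).  Missing covariates band to NaN.
    """
    ref = pd.Timestamp(reference_date)
    dob = pd.to_datetime(covariates["dob"])
    age = (ref - dob).dt.days / 365.25
    age_band = pd.cut(
        age, bins=[-np.inf, 18, 65, np.inf], right=False, labels=AGE_BANDS
    ).astype(object)

    sex = covariates["sex"].astype(str).str.strip().str.lower()
    sex_band = sex.where(sex.isin(SEX_BANDS), other=np.nan)

    svi = pd.to_numeric(covariates["svi_score"], errors="coerce")
    svi_band = pd.cut(
        svi, bins=[-0.001, 25, 50, 75, 100], labels=SVI_BANDS
    ).astype(object)

    ruca = pd.to_numeric(covariates["ruca_code"], errors="coerce")
    ruca_band = pd.cut(
        ruca, bins=[0.5, 3.5, 6.5, 9.5, 10.5], labels=RUCA_BANDS
    ).astype(object)

    out = pd.DataFrame(
        {
            "person_key": covariates["person_key"].values,
            "age_band": age_band.values,
            "sex_band": sex_band.values,
            "svi_band": svi_band.values,
            "ruca_band": ruca_band.values,
        }
    )
    return out


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, alpha_adjusted: float = 0.05
) -> dict:
    """Two-sample test for equality of proportions with continuity correction.

    Returns the difference p1 − p2 in percentage points, a
    continuity-corrected interval at the adjusted level, and the Yates
    chi-square p-value — the classic prop.test-style analysis.
    """
    if n1 < 1 or n2 < 1:
        raise UndefinedRateError("both sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts out of range")
    p1, p2 = k1 / n1, k2 / n2
    diff = p1 - p2
    z = norm.ppf(1 - alpha_adjusted / 2.0)
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    cc = 0.5 * (1.0 / n1 + 1.0 / n2)
    half = z * se + cc
    # Yates-corrected chi-square on the 2x2 table
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum @ colsum / table.sum()
    adj = np.minimum(np.abs(table - expected), 0.5)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = float(np.nansum((np.abs(table - expected) - adj) ** 2 / expected))
    p_value = float(chi2.sf(stat, df=1))
    return {
        "diff_pp": 100.0 * diff,
        "lower_pp": 100.0 * (diff - half),
        "upper_pp": 100.0 * (diff + half),
        "statistic": stat,
        "p_value": p_value,
    }


def demographic_contrasts(
    profiles: pd.DataFrame,
    records: pd.DataFrame,
    alpha_family: float = 0.05,
    n_comparisons: int = 39,
) -> pd.DataFrame:
    """All 39 pairwise characteristic comparisons across the three groups.

    ``profiles`` is the output of :func:`band_covariates`; ``records`` a
    concordance record table.  Each of the 13 levels is compared across the
    3 group pairs at alpha ``alpha_family / n_comparisons``.  Denominators
    are full group sizes (published-table convention: missing-covariate rows
    are omitted, not excluded from denominators); a level with no members in any
    group is skipped.
    """
    recs = records.copy()
    status = classify_table(recs, allow_partial=False)
    group = pd.Series(
        np.select(
            [
                status == Status.NONREPORTING.value,
                status == Status.DISCORDANT.value,
            ],
            ["nonreporting", "discordant"],
            default="concordant",
        ),
        index=recs.index,
    )
    merged = pd.DataFrame(
        {"person_key": recs["person_key"].values, "group": group.values}
    ).merge(profiles, on="person_key", how="left")

    sizes = merged["group"].value_counts()
    for g in ("concordant", "discordant", "nonreporting"):
        if sizes.get(g, 0) == 0:
            raise UndefinedRateError(f"empty comparison group {g!r}")

    alpha = alpha_family / n_comparisons
    rows = []
    for axis, level in LEVELS:
        in_level = merged[axis] == level
        if not in_level.any():
            continue  # level missing for all persons: skipped, logged upstream
        ks = merged.loc[in_level, "group"].value_counts()
        for ga, gb in GROUP_PAIRS:
            res = two_proportion_test(
                int(ks.get(ga, 0)), int(sizes[ga]),
                int(ks.get(gb, 0)), int(sizes[gb]),
                alpha,
            )
            rows.append(
                {
                    "characteristic": axis,
                    "level": level,
                    "group_a": ga,
                    "group_b": gb,
                    "k_a": int(ks.get(ga, 0)),
                    "n_a": int(sizes[ga]),
                    "k_b": int(ks.get(gb, 0)),
                    "n_b": int(sizes[gb]),
                    **res,
                    "significant": res["p_value"] < alpha,
                }
            )
    return pd.DataFrame(rows)


def practice_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """Per-practice size, discordance rate, missingness rate, non-White share.

    ``records`` must carry a ``practice_key`` column.  Discordance rate is
    among reporting patients of the practice (NaN if none report);
    ``nonwhite_share`` uses the census labeling.
    """
    recs = records.copy()
    status = classify_table(recs, allow_partial=False).to_numpy()
    recs["_disc"] = status == Status.DISCORDANT.value
    recs["_miss"] = status == Status.NONREPORTING.value
    recs["_nonwhite"] = recs["census_category"] != Category.WHITE.value
    g = recs.groupby("practice_key")
    out = pd.DataFrame(
        {
            "n_patients": g.size(),
            "missingness_rate": g["_miss"].mean(),
            "nonwhite_share": g["_nonwhite"].mean(),
        }
    )
    reporting = recs[~recs["_miss"]].groupby("practice_key")["_disc"].mean()
    out["discordance_rate"] = reporting
    return out.reset_index()


#: Default model set: size effects, the missingness-discordance relation, and
#: the patient-mix heterogeneity models.
DEFAULT_MODELS: tuple[tuple, ...] = (
    ("discordance_rate", "n_patients"),
    ("missingness_rate", "n_patients"),
    ("discordance_rate", "missingness_rate"),
    ("discordance_rate", "nonwhite_share"),
    ("missingness_rate", "nonwhite_share"),
)


def practice_regressions(
    summaries: pd.DataFrame,
    model_set: Sequence[tuple] = DEFAULT_MODELS,
) -> pd.DataFrame:
    """Simple OLS fits y ~ x across practices for each (y, x) model.

    Each row reports slope, standard error, two-sided p and R².  A constant
    regressor yields a degenerate-fit row (NaNs, flagged) for that model
    only.  Requires at least 3 practices.
    """
    import statsmodels.api as sm

    if len(summaries) < 3:
        raise ValueError("need >= 3 practices for practice-level regression")
    rows = []
    for y_col, x_col in model_set:
        sub = summaries[[y_col, x_col]].dropna()
        x = sub[x_col].to_numpy(dtype=float)
        y = sub[y_col].to_numpy(dtype=float)
        if len(sub) < 3 or np.ptp(x) == 0:
            rows.append(
                {
                    "response": y_col, "regressor": x_col, "n": len(sub),
                    "slope": np.nan, "stderr": np.nan, "p_value": np.nan,
                    "r_squared": np.nan, "degenerate": True,
                }
            )
            continue
        res = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append(
            {
                "response": y_col, "regressor": x_col, "n": len(sub),
                "slope": float(res.params[1]),
                "stderr": float(res.bse[1]),
                "p_value": float(res.pvalues[1]),
                "r_squared": float(res.rsquared),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)


def concentration_report(
    records: pd.DataFrame,
    pattern_mask: pd.Series,
    top_n_practices: int = 10,
) -> dict:
    """Share of a discordance pattern's members in its top practices.

    ``pattern_mask`` selects the pattern members within ``records`` (e.g.
    EHR non-Hispanic but census Hispanic).  Practices are ranked by member
    count; the report gives the share of members contributed by the top
    ``top_n_practices``.
    """
    members = records[pattern_mask.reindex(records.index, fill_value=False)]
    total = len(members)
    if total == 0:
        raise UndefinedRateError("pattern has no members")
    by_practice = (
        members.groupby("practice_key").size().sort_values(ascending=False)
    )
    top = by_practice.iloc[:top_n_practices]
    return {
        "n_members": total,
        "n_practices": int(by_practice.size),
        "top_n": int(min(top_n_practices, by_practice.size)),
        "n_in_top": int(top.sum()),
        "share_in_top": float(top.sum() / total),
        "top_practices": top.index.tolist(),
    }


def zero_multiracial_practices(
    records: pd.DataFrame, min_patients: int = 1000
) -> pd.DataFrame:
    """Large practices recording zero Multiracial patients in the EHR.

    Returns those practices with their sizes plus the count of their patients
    who are single-race in the EHR but Multiracial in the census source —
    the screen for a missing multi-select option.
    """
    multi = Category.MULTIRACIAL.value
    g = records.groupby("practice_key")
    size = g.size()
    has_multi = g["ehr_category"].agg(lambda s: (s == multi).any())
    flagged = size[(size > min_patients) & ~has_multi]
    single_vs_multi = (
        records["ehr_category"].isin([c.value for c in SINGLE_RACES])
        & (records["census_category"] == multi)
    )
    pat = records[single_vs_multi].groupby("practice_key").size()
    return pd.DataFrame(
        {
            "practice_key": flagged.index,
            "n_patients": flagged.values,
            "n_single_vs_census_multiracial": pat.reindex(flagged.index, fill_value=0).values,
        }
    )
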