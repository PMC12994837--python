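"""Group prevalence, labeling-source prevalence shifts, and intervals.

Estimands
---------
For each racial/ethnic group *g* and 3-digit outcome group *o* we estimate
the prevalence ``p = k/n`` (ever-indicator mean) under either labeling
source (EHR-recorded or census-recorded group membership), with a
continuity-corrected Wilson score interval at a Bonferroni-adjusted level.

The *prevalence shift* for (g, o) is the percentage-point change
``100 * (p_census - p_ehr)`` when group membership switches from the EHR to
the census labeling.  Its interval comes from a logistic regression on the
stacked denominators (intercept + labeling-source indicator), transformed to
the probability-difference scale by the delta method; because many persons
belong to both denominators, the variance is person-clustered (sandwich).
Weights default to 1 — the estimand is then exactly the difference of the
two group proportions — but a weight column is accepted for generality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .categories import Category, REPORTED_CATEGORIES
from .concordance import Status, UndefinedRateError, classify_table

__all__ = [
    "wilson_ci",
    "bonferroni_level",
    "group_prevalence",
    "ShiftEstimate",
    "prevalence_shift",
    "prevalence_shift_table",
    "disaggregate_patterns",
]


def wilson_ci(numerator, denominator, alpha: float = 0.05):
    """Continuity-corrected Wilson score interval for a binomial proportion.

    Accepts scalars or arrays.  The boundary rules are exact: lower = 0 when
    the numerator is 0 and upper = 1 when numerator = denominator; otherwise
    the closed-form corrected bounds, clipped to [0, 1].
    """
    k = np.asarray(numerator, dtype=float)
    n = np.asarray(denominator, dtype=float)
    if np.any(n < 1):
        raise UndefinedRateError("denominator must be >= 1")
    if np.any((k < 0) | (k > n)):
        raise ValueError("numerator must lie in [0, denominator]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z = norm.ppf(1 - alpha / 2.0)
    p = k / n
    q = 1.0 - p
    denom = 2.0 * (n + z * z)
    with np.errstate(invalid="ignore"):
        lo_rad = np.sqrt(np.maximum(z * z - 2.0 - 1.0 / n + 4.0 * p * (n * q + 1.0), 0.0))
        hi_rad = np.sqrt(np.maximum(z * z + 2.0 - 1.0 / n + 4.0 * p * (n * q - 1.0), 0.0))
        lower = (2.0 * n * p + z * z - 1.0 - z * lo_rad) / denom
        upper = (2.0 * n * p + z * z + 1.0 + z * hi_rad) / denom
    lower = np.where(k == 0, 0.0, np.clip(lower, 0.0, 1.0))
    upper = np.where(k == n, 1.0, np.clip(upper, 0.0, 1.0))
    if np.isscalar(numerator) and np.isscalar(denominator):
        return float(lower), float(upper)
    return lower, upper


def bonferroni_level(alpha_family: float, n_comparisons: int) -> float:
    """Per-comparison alpha for a family-wise error rate over n comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha_family / n_comparisons


def group_prevalence(
    labels: pd.Series,
    outcome_matrix: pd.DataFrame,
    labeling: str,
    alpha_adjusted: float = 0.05,
    groups: Sequence = REPORTED_CATEGORIES,
    outcomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per group x outcome prevalence with adjusted Wilson intervals.

    ``labels`` maps person_key → category (indexed by person); persons whose
    label is Unreported never form a group (relevant under the EHR labeling).
    Empty groups are skipped.  Returns a tidy frame with columns
    group, outcome_group, labeling, n, k, p, lower, upper.
    """
    if outcomes is None:
        outcomes = list(outcome_matrix.columns)
    mat = outcome_matrix.reindex(labels.index, fill_value=0)
    rows = []
    for g in groups:
        g = Category(g)
        if g is Category.UNREPORTED:
            continue
        members = labels.index[labels == g.value]
        n = len(members)
        if n == 0:
            continue
        sub = mat.loc[members, outcomes]
        ks = sub.sum(axis=0)
        lo, hi = wilson_ci(ks.values, np.full(len(outcomes), n), alpha_adjusted)
        for j, o in enumerate(outcomes):
            rows.append(
                {
                    "group": g.value,
                    "outcome_group": o,
                    "labeling": labeling,
                    "n": n,
                    "k": int(ks.iloc[j]),
                    "p": ks.iloc[j] / n,
                    "lower": lo[j],
                    "upper": hi[j],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ShiftEstimate:
    """Percentage-point prevalence shift census-labeled minus EHR-labeled."""

    group: str
    outcome_group: str
    delta_pp: float
    ci_pp: tuple
    p_ehr: float
    p_census: float
    n_ehr: int
    n_census: int
    n_overlap: int
    method: str = "logit-delta"
    one_sided: bool = False


def _delta_from_logit(y, src, clusters, alpha):
    """Fit y ~ 1 + src by logistic ML, delta-method CI for p1 - p0."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(src, dtype=float), src.astype(float)])
    model = sm.GLM(y.astype(float), X, family=sm.families.Binomial())
    res = model.fit(cov_type="cluster", cov_kwds={"groups": clusters})
    b0, b1 = res.params
    V = res.cov_params()
    V = V.values if hasattr(V, "values") else np.asarray(V)
    p0, p1 = expit(b0), expit(b0 + b1)
    g = np.array([p1 * (1 - p1) - p0 * (1 - p0), p1 * (1 - p1)])
    var = float(g @ V @ g)
    z = norm.ppf(1 - alpha / 2.0)
    delta = p1 - p0
    half = z * np.sqrt(max(var, 0.0))
    return delta, (delta - half, delta + half)


def prevalence_shift(
    labels_ehr: pd.Series,
    labels_census: pd.Series,
    outcome: pd.Series,
    group,
    outcome_group: str = "",
    alpha_adjusted: float = 0.05,
) -> ShiftEstimate:
    """Shift in one group's outcome prevalence between labeling sources.

    ``labels_ehr`` / ``labels_census`` map person_key → category;
    ``outcome`` maps person_key → 0/1 ever-indicator and must cover every
    person appearing in either labeling.  When one denominator is degenerate
    (all events or none) the logistic fit is replaced by the closed-form
    normal difference-of-proportions interval (``method`` records this).
    """
    g = Category(group).value
    idx_e = labels_ehr.index[labels_ehr == g]
    idx_c = labels_census.index[labels_census == g]
    n_e, n_c = len(idx_e), len(idx_c)
    overlap = len(idx_e.intersection(idx_c))
    one_sided = n_e == 0 or n_c == 0
    y_e = outcome.reindex(idx_e).to_numpy(dtype=float) if n_e else np.empty(0)
    y_c = outcome.reindex(idx_c).to_numpy(dtype=float) if n_c else np.empty(0)
    p_e = float(y_e.mean()) if n_e else float("nan")
    p_c = float(y_c.mean()) if n_c else float("nan")

    if one_sided:
        # emit the available side; the shift itself is undefined
        return ShiftEstimate(
            g, outcome_group, float("nan"), (float("nan"), float("nan")),
            p_e, p_c, n_e, n_c, overlap, method="one-sided", one_sided=True,
        )

    degenerate = p_e in (0.0, 1.0) or p_c in (0.0, 1.0)
    if degenerate:
        z = norm.ppf(1 - alpha_adjusted / 2.0)
        var = p_e * (1 - p_e) / n_e + p_c * (1 - p_c) / n_c
        delta = p_c - p_e
        half = z * np.sqrt(var)
        ci = (delta - half, delta + half)
        method = "normal-fallback"
    else:
        y = np.concatenate([y_e, y_c])
        src = np.concatenate([np.zeros(n_e), np.ones(n_c)])
        clusters = np.concatenate([idx_e.to_numpy(), idx_c.to_numpy()])
        delta, ci = _delta_from_logit(y, src, clusters, alpha_adjusted)
        method = "logit-delta"

    return ShiftEstimate(
        g, outcome_group, 100.0 * delta, (100.0 * ci[0], 100.0 * ci[1]),
        p_e, p_c, n_e, n_c, overlap, method=method,
    )


def prevalence_shift_table(
    labels_ehr: pd.Series,
    labels_census: pd.Series,
    outcome_matrix: pd.DataFrame,
    outcomes: Sequence[str],
    groups: Sequence = REPORTED_CATEGORIES,
    alpha_family: float = 0.05,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Shift estimates for every group x outcome at the adjusted level.

    ``n_comparisons`` defaults to the family size actually produced
    (len(groups w/o Unreported) x len(outcomes)).
    """
    groups = [Category(g) for g in groups if Category(g) is not Category.UNREPORTED]
    if n_comparisons is None:
        n_comparisons = len(groups) * len(outcomes)
    alpha = bonferroni_level(alpha_family, n_comparisons)
    rows = []
    for o in outcomes:
        y = outcome_matrix[o]
        for g in groups:
            est = prevalence_shift(labels_ehr, labels_census, y, g, o, alpha)
            rows.append(
                {
                    "group": est.group,
                    "outcome_group": o,
                    "delta_pp": est.delta_pp,
                    "lower_pp": est.ci_pp[0],
                    "upper_pp": est.ci_pp[1],
                    "p_ehr": est.p_ehr,
                    "p_census": est.p_census,
                    "n_ehr": est.n_ehr,
                    "n_census": est.n_census,
                    "n_overlap": est.n_overlap,
                    "method": est.method,
                }
            )
    return pd.DataFrame(rows)


def disaggregate_patterns(
    records: pd.DataFrame,
    outcome: pd.Series,
    focus_groups: Sequence[tuple],
    alpha_adjusted: float = 0.05,
    allow_partial: bool = False,
) -> pd.DataFrame:
    """Decompose focus aggregates into their recording-pattern constituents.

    ``focus_groups`` is a list of ``(labeling, category)`` pairs such as
    ``[("CENSUS", "NHPI"), ("EHR", "NHPI"), ("CENSUS", "White"), ("EHR",
    "White")]``.  For each aggregate, constituents are the distinct
    counterpart labels (including Unreported on the EHR side) with their
    concordance status; constituent member counts partition the aggregate.
    Each row carries count, prevalence and a Wilson interval.
    """
    if not focus_groups:
        raise ValueError("focus_groups must be nonempty")
    recs = records.copy()
    recs["status"] = classify_table(recs, allow_partial=allow_partial)
    rows = []
    for labeling, cat in focus_groups:
        labeling = labeling.upper()
        cat = Category(cat).value
        own_col = "ehr_category" if labeling == "EHR" else "census_category"
        other_col = "census_category" if labeling == "EHR" else "ehr_category"
        agg = recs[recs[own_col] == cat]
        if agg.empty:
            continue
        y_agg = outcome.reindex(agg["person_key"]).to_numpy(dtype=float)
        n_agg, k_agg = len(agg), int(np.nansum(y_agg))
        lo, hi = wilson_ci(k_agg, n_agg, alpha_adjusted)
        rows.append(
            {
                "labeling": labeling, "group": cat,
                "counterpart": "(aggregate)", "status": "(aggregate)",
                "n": n_agg, "k": k_agg, "p": k_agg / n_agg,
                "lower": lo, "upper": hi,
            }
        )
        for (other, status), sub in agg.groupby([other_col, "status"], sort=True):
            y = outcome.reindex(sub["person_key"]).to_numpy(dtype=float)
            n, k = len(sub), int(np.nansum(y))
            lo, hi = wilson_ci(k, n, alpha_adjusted)
            rows.append(
                {
                    "labeling": labeling, "group": cat,
                    "counterpart": other, "status": status,
                    "n": n, "k": k, "p": k / n,
                    "lower": lo, "upper": hi,
                }
            )
    return pd.DataFrame(rows)
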