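"""Wilson intervals, Bonferroni adjustment, prevalence shifts, patterns."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from concordkit.concordance import UndefinedRateError
from concordkit.estimation import (
    bonferroni_level,
    disaggregate_patterns,
    group_prevalence,
    prevalence_shift,
    prevalence_shift_table,
    wilson_ci,
)


def wilson_cc_oracle(k, n, alpha):
    """Independent oracle: numeric roots of the continuity-corrected score
    equations |p̂ - p| - 1/(2n) = z sqrt(p(1-p)/n)."""
    z = norm.ppf(1 - alpha / 2)
    phat = k / n
    if k == 0:
        lower = 0.0
    else:
        f = lambda p: (phat - p - 1 / (2 * n)) - z * np.sqrt(p * (1 - p) / n)
        lower = brentq(f, 1e-15, phat, xtol=1e-14) if f(1e-15) > 0 else 0.0
    if k == n:
        upper = 1.0
    else:
        g = lambda p: (p - phat - 1 / (2 * n)) - z * np.sqrt(p * (1 - p) / n)
        upper = brentq(g, phat, 1 - 1e-15, xtol=1e-14) if g(1 - 1e-15) > 0 else 1.0
    return max(lower, 0.0), min(upper, 1.0)


class TestWilson:
    def test_boundary_rules(self):
        lo, hi = wilson_ci(0, 10, 0.05)
        assert lo == 0.0 and hi < 1
        lo, hi = wilson_ci(10, 10, 0.05)
        assert hi == 1.0 and lo > 0

    def test_symmetry_at_half(self):
        lo, hi = wilson_ci(5, 10, 0.05)
        assert abs((1 - hi) - lo) < 1e-9

    def test_closed_form_matches_score_equation_roots(self):
        """Textbook case plus a random sweep against the numeric oracle."""
        lo, hi = wilson_ci(81, 263, 0.05)
        olo, ohi = wilson_cc_oracle(81, 263, 0.05)
        assert abs(lo - olo) < 1e-10 and abs(hi - ohi) < 1e-10
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 5000))
            k = int(rng.integers(0, n + 1))
            alpha = float(rng.uniform(0.0005, 0.2))
            lo, hi = wilson_ci(k, n, alpha)
            olo, ohi = wilson_cc_oracle(k, n, alpha)
            assert abs(lo - olo) < 1e-10, (k, n, alpha)
            assert abs(hi - ohi) < 1e-10, (k, n, alpha)

    def test_vectorized_matches_scalar(self):
        ks = np.array([0, 3, 9]);  ns = np.array([4, 10, 9])
        lo, hi = wilson_ci(ks, ns, 0.01)
        for i in range(3):
            slo, shi = wilson_ci(int(ks[i]), int(ns[i]), 0.01)
            assert np.isclose(lo[i], slo) and np.isclose(hi[i], shi)

    def test_zero_denominator_rejected(self):
        with pytest.raises(UndefinedRateError):
            wilson_ci(0, 0, 0.05)


class TestBonferroni:
    def test_values(self):
        assert bonferroni_level(0.05, 1) == 0.05
        assert np.isclose(bonferroni_level(0.05, 350), 0.05 / 350)
        assert np.isclose(bonferroni_level(0.05, 39), 0.05 / 39)

    def test_wider_family_never_narrows_intervals(self):
        widths = []
        for m in (1, 10, 350):
            lo, hi = wilson_ci(40, 200, bonferroni_level(0.05, m))
            widths.append(hi - lo)
        assert widths[0] <= widths[1] <= widths[2]


class TestGroupPrevalence:
    def test_all_positive_group_hits_one(self):
        labels = pd.Series(["NHPI"] * 8, index=range(8))
        mat = pd.DataFrame({"E11": [1] * 8}, index=range(8))
        out = group_prevalence(labels, mat, "CENSUS", 0.05)
        row = out.iloc[0]
        assert row["p"] == 1.0 and row["upper"] == 1.0

    def test_matches_hand_tally_on_fixture(self):
        rng = np.random.default_rng(1)
        labels = pd.Series(rng.choice(["White", "Black"], 50), index=range(50))
        mat = pd.DataFrame({"E11": rng.integers(0, 2, 50)}, index=range(50))
        out = group_prevalence(labels, mat, "EHR", 0.05).set_index("group")
        for g in ("White", "Black"):
            members = labels.index[labels == g]
            assert out.loc[g, "n"] == len(members)
            assert out.loc[g, "k"] == mat.loc[members, "E11"].sum()

    def test_unreported_never_forms_a_group(self):
        labels = pd.Series(["White", "Unreported"], index=[0, 1])
        mat = pd.DataFrame({"E11": [1, 1]}, index=[0, 1])
        out = group_prevalence(labels, mat, "EHR", 0.05)
        assert set(out["group"]) == {"White"}


def _shift_fixture(seed=7, p_extra=0.35):
    rng = np.random.default_rng(seed)
    n_ov, n_e, n_c = 400, 100, 100
    persons = np.arange(n_ov + n_e + n_c)
    p = np.full(len(persons), 0.15)
    p[n_ov + n_e:] = p_extra
    y = pd.Series((rng.random(len(persons)) < p).astype(float), index=persons)
    idx_e = np.concatenate([persons[:n_ov], persons[n_ov:n_ov + n_e]])
    idx_c = np.concatenate([persons[:n_ov], persons[n_ov + n_e:]])
    labels_e = pd.Series("NHPI", index=pd.Index(idx_e))
    labels_c = pd.Series("NHPI", index=pd.Index(idx_c))
    return labels_e, labels_c, y, idx_e, idx_c


class TestPrevalenceShift:
    def test_identical_labelings_give_zero_covering_interval(self):
        labels_e, _, y, idx_e, _ = _shift_fixture()
        est = prevalence_shift(labels_e, labels_e.copy(), y, "NHPI", "E11", 0.05)
        assert abs(est.delta_pp) < 1e-9
        assert est.ci_pp[0] - 1e-9 <= 0.0 <= est.ci_pp[1] + 1e-9

    def test_point_estimate_is_exact_proportion_difference(self):
        labels_e, labels_c, y, idx_e, idx_c = _shift_fixture()
        est = prevalence_shift(labels_e, labels_c, y, "NHPI", "E11", 0.05)
        manual = y.loc[idx_c].mean() - y.loc[idx_e].mean()
        assert abs(est.delta_pp / 100 - manual) < 1e-12
        assert abs((est.p_census - est.p_ehr) - manual) < 1e-12

    def test_interval_agrees_with_person_resampling_bootstrap(self):
        """Delta-method width within 15% of a 2,000-replicate cluster
        bootstrap on the same cohort."""
        labels_e, labels_c, y, idx_e, idx_c = _shift_fixture()
        est = prevalence_shift(labels_e, labels_c, y, "NHPI", "E11", 0.05)
        rng = np.random.default_rng(99)
        yv = y.to_numpy()
        in_e = np.zeros(len(y), bool); in_e[idx_e] = True
        in_c = np.zeros(len(y), bool); in_c[idx_c] = True
        take = rng.integers(0, len(y), size=(2000, len(y)))
        boots = np.empty(2000)
        for b in range(2000):
            t = take[b]
            boots[b] = yv[t][in_c[t]].mean() - yv[t][in_e[t]].mean()
        blo, bhi = np.percentile(boots, [2.5, 97.5]) * 100
        width_ratio = (est.ci_pp[1] - est.ci_pp[0]) / (bhi - blo)
        assert 0.85 < width_ratio < 1.15

    def test_degenerate_group_falls_back_to_normal_interval(self):
        y = pd.Series([0.0] * 20 + [1.0] * 5, index=range(25))
        le = pd.Series("White", index=pd.Index(range(20)))
        lc = pd.Series("White", index=pd.Index(range(20, 25)))
        est = prevalence_shift(le, lc, y, "White", "E11", 0.05)
        assert est.method == "normal-fallback"
        assert est.delta_pp == 100.0

    def test_one_sided_group_flagged(self):
        y = pd.Series([0.0, 1.0], index=[0, 1])
        le = pd.Series("NHPI", index=pd.Index([], dtype=int))
        lc = pd.Series("NHPI", index=pd.Index([0, 1]))
        est = prevalence_shift(le, lc, y, "NHPI", "E11", 0.05)
        assert est.one_sided and np.isnan(est.delta_pp)
        assert est.p_census == 0.5

    def test_table_covers_all_groups_and_outcomes(self, small_records, small_matrix):
        ehr_lab = small_records.set_index("person_key")["ehr_category"]
        ehr_lab = ehr_lab[ehr_lab != "Unreported"]
        cen_lab = small_records.set_index("person_key")["census_category"]
        table = prevalence_shift_table(
            ehr_lab, cen_lab, small_matrix, ["E11", "I10"]
        )
        assert set(table["outcome_group"]) == {"E11", "I10"}
        ok = table.dropna(subset=["delta_pp"])
        assert np.allclose(
            ok["delta_pp"] / 100, ok["p_census"] - ok["p_ehr"], atol=1e-12
        )


class TestDisaggregation:
    def test_constituents_partition_each_aggregate(self, small_records, small_matrix):
        out = disaggregate_patterns(
            small_records, small_matrix["E11"],
            [("CENSUS", "NHPI"), ("EHR", "White"), ("CENSUS", "White")],
        )
        for (labeling, group), sub in out.groupby(["labeling", "group"]):
            agg = sub[sub["counterpart"] == "(aggregate)"].iloc[0]
            parts = sub[sub["counterpart"] != "(aggregate)"]
            assert parts["n"].sum() == agg["n"]
            assert parts["k"].sum() == agg["k"]

    def test_pattern_prevalences_recombine_as_weighted_mean(
        self, small_records, small_matrix
    ):
        out = disaggregate_patterns(
            small_records, small_matrix["E11"], [("CENSUS", "White")]
        )
        agg = out[out["counterpart"] == "(aggregate)"].iloc[0]
        parts = out[out["counterpart"] != "(aggregate)"]
        recombined = (parts["p"] * parts["n"]).sum() / parts["n"].sum()
        assert abs(recombined - agg["p"]) < 1e-12

    def test_single_pattern_aggregate_equals_itself(self):
        records = pd.DataFrame(
            {
                "person_key": [0, 1],
                "ehr_races": ["NHPI", "NHPI"],
                "ehr_category": ["NHPI", "NHPI"],
                "census_races": ["NHPI", "NHPI"],
                "census_category": ["NHPI", "NHPI"],
            }
        )
        y = pd.Series([1.0, 0.0], index=[0, 1])
        out = disaggregate_patterns(records, y, [("CENSUS", "NHPI")])
        assert len(out) == 2  # aggregate + its single constituent
        assert out.iloc[0]["n"] == out.iloc[1]["n"] == 2

    def test_empty_focus_rejected(self, small_records, small_matrix):
        with pytest.raises(ValueError):
            disaggregate_patterns(small_records, small_matrix["E11"], [])
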