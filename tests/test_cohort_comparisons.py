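"""Concordance-group demographic contrasts and practice-level analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, norm

from concordkit.cohort_comparisons import (
    DEFAULT_MODELS,
    LEVELS,
    band_covariates,
    concentration_report,
    practice_regressions,
    practice_summaries,
    demographic_contrasts,
    two_proportion_test,
    zero_multiracial_practices,
)
from concordkit.concordance import UndefinedRateError


class TestTwoProportion:
    def test_equal_proportions_give_zero_diff(self):
        res = two_proportion_test(20, 100, 40, 200, 0.05)
        assert res["diff_pp"] == 0.0
        assert res["lower_pp"] < 0 < res["upper_pp"]

    def test_published_age_contrast(self):
        """Concordant vs discordant 65+ shares: 13.6 pp, CI [13.4, 13.8]."""
        res = two_proportion_test(
            1_547_780, 4_344_600, 83_240, 378_060, 0.05 / 39
        )
        assert round(res["diff_pp"], 1) == 13.6
        assert round(res["lower_pp"], 1) == 13.4
        assert round(res["upper_pp"], 1) == 13.8

    def test_p_value_matches_independent_chi_square_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n1, n2 = int(rng.integers(5, 500)), int(rng.integers(5, 500))
            k1, k2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            res = two_proportion_test(k1, n1, k2, n2, 0.05)
            table = [[k1, n1 - k1], [k2, n2 - k2]]
            oracle = chi2_contingency(table, correction=True)
            assert abs(res["p_value"] - oracle.pvalue) < 1e-10, (k1, n1, k2, n2)

    def test_ci_matches_closed_form_oracle(self):
        """CI = diff ± (z·SE + continuity term), typed independently."""
        k1, n1, k2, n2, alpha = 81, 263, 40, 190, 0.01
        res = two_proportion_test(k1, n1, k2, n2, alpha)
        p1, p2 = k1 / n1, k2 / n2
        z = norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2) \
            + 0.5 * (1 / n1 + 1 / n2)
        assert abs(res["lower_pp"] - 100 * (p1 - p2 - half)) < 1e-10
        assert abs(res["upper_pp"] - 100 * (p1 - p2 + half)) < 1e-10

    def test_zero_sample_rejected(self):
        with pytest.raises(UndefinedRateError):
            two_proportion_test(0, 0, 1, 10, 0.05)


class TestBanding:
    def test_bands(self):
        cov = pd.DataFrame(
            {
                "person_key": [0, 1, 2, 3, 4],
                "dob": ["2010-06-01", "1980-01-01", "1940-01-01",
                        "2000-01-01", "1990-01-01"],
                "sex": ["male", "female", "FEMALE", "other", "male"],
                "svi_score": [0.0, 25.0, 25.1, 99.9, np.nan],
                "ruca_code": [1, 4, 7, 10, np.nan],
            }
        )
        out = band_covariates(cov, reference_date="2021-12-31")
        assert list(out["age_band"]) == ["<18", "18-64", ">=65", "18-64", "18-64"]
        assert list(out["sex_band"].fillna("NA")) == [
            "male", "female", "female", "NA", "male"]
        assert list(out["svi_band"].fillna("NA")) == [
            "[0,25]", "[0,25]", "(25,50]", "(75,100]", "NA"]
        assert list(out["ruca_band"].fillna("NA")) == [
            "metropolitan", "micropolitan", "small town", "rural", "NA"]


def _grouped_records(n_conc=200, n_disc=100, n_miss=100, seed=0):
    rng = np.random.default_rng(seed)
    n = n_conc + n_disc + n_miss
    ehr = ["White"] * n_conc + ["Black"] * n_disc + ["Unreported"] * n_miss
    return pd.DataFrame(
        {
            "person_key": np.arange(n),
            "practice_key": rng.integers(0, 10, n),
            "ehr_races": ehr,
            "ehr_category": ehr,
            "census_races": ["White"] * n,
            "census_category": ["White"] * n,
        }
    )


class TestTable2:
    def _profiles(self, n, seed=1):
        rng = np.random.default_rng(seed)
        return band_covariates(
            pd.DataFrame(
                {
                    "person_key": np.arange(n),
                    "dob": pd.Timestamp("2021-12-31")
                    - pd.to_timedelta(rng.uniform(0, 90 * 365.25, n), unit="D"),
                    "sex": rng.choice(["male", "female"], n),
                    "svi_score": rng.uniform(0, 100, n),
                    "ruca_code": rng.integers(1, 11, n).astype(float),
                }
            )
        )

    def test_row_count_is_exactly_39(self):
        records = _grouped_records()
        out = demographic_contrasts(self._profiles(len(records)), records)
        assert len(out) == 39
        assert len(LEVELS) == 13

    def test_identical_compositions_give_near_zero_diffs(self):
        records = _grouped_records(2000, 2000, 2000)
        # same covariate distribution in all groups: no diff is significant
        out = demographic_contrasts(self._profiles(6000, seed=2), records)
        assert not out["significant"].any()

    def test_diffs_antisymmetric_under_pair_reversal(self):
        records = _grouped_records()
        profiles = self._profiles(len(records))
        out = demographic_contrasts(profiles, records)
        for _, row in out.head(6).iterrows():
            rev = two_proportion_test(
                row["k_b"], row["n_b"], row["k_a"], row["n_a"], 0.05 / 39
            )
            assert np.isclose(rev["diff_pp"], -row["diff_pp"])

    def test_empty_group_rejected(self):
        records = _grouped_records(n_disc=0)
        with pytest.raises(UndefinedRateError):
            demographic_contrasts(self._profiles(len(records)), records)


class TestPracticeRegressions:
    def test_exact_linear_relation_recovered(self):
        df = pd.DataFrame(
            {
                "practice_key": range(5),
                "n_patients": [1.0, 2, 3, 4, 5],
                "discordance_rate": [2.0, 4, 6, 8, 10],
                "missingness_rate": [0.1] * 5,
                "nonwhite_share": [0.2, 0.3, 0.4, 0.5, 0.6],
            }
        )
        out = practice_regressions(
            df, [("discordance_rate", "n_patients")]
        ).iloc[0]
        assert np.isclose(out["slope"], 2.0)
        assert out["p_value"] < 1e-6

    def test_slope_equals_closed_form_ols(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "practice_key": range(40),
                "n_patients": rng.integers(10, 500, 40).astype(float),
                "discordance_rate": rng.uniform(0, 0.2, 40),
                "missingness_rate": rng.uniform(0, 0.4, 40),
                "nonwhite_share": rng.uniform(0, 1, 40),
            }
        )
        out = practice_regressions(df).set_index(["response", "regressor"])
        for y_col, x_col in DEFAULT_MODELS:
            x, y = df[x_col].to_numpy(), df[y_col].to_numpy()
            slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
            assert abs(out.loc[(y_col, x_col), "slope"] - slope) < 1e-10

    def test_null_slope_p_values_are_uniform(self):
        """Independent noise regressor: p-values over seeds look uniform."""
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(300):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            df = pd.DataFrame(
                {
                    "practice_key": range(30),
                    "n_patients": x,
                    "discordance_rate": y,
                    "missingness_rate": y,
                    "nonwhite_share": x,
                }
            )
            out = practice_regressions(df, [("discordance_rate", "n_patients")])
            pvals.append(out.iloc[0]["p_value"])
        pvals = np.sort(pvals)
        # Kolmogorov distance from uniform stays small
        dist = np.max(np.abs(pvals - np.arange(1, 301) / 301))
        assert dist < 0.1

    def test_constant_regressor_degenerates_only_that_model(self):
        df = pd.DataFrame(
            {
                "practice_key": range(5),
                "n_patients": [10.0] * 5,
                "discordance_rate": [0.1, 0.2, 0.3, 0.4, 0.5],
                "missingness_rate": [0.2, 0.1, 0.3, 0.2, 0.4],
                "nonwhite_share": [0.1, 0.2, 0.3, 0.4, 0.5],
            }
        )
        out = practice_regressions(df)
        flags = out.set_index(["response", "regressor"])["degenerate"]
        assert flags[("discordance_rate", "n_patients")]
        assert not flags[("discordance_rate", "nonwhite_share")]

    def test_too_few_practices_rejected(self):
        with pytest.raises(ValueError):
            practice_regressions(pd.DataFrame({"practice_key": [1, 2]}))

    def test_heterogeneity_slope_positive_on_synthetic_practices(
        self, small_records
    ):
        """Practices with more non-White patients show more discordance."""
        summaries = practice_summaries(small_records)
        out = practice_regressions(
            summaries, [("discordance_rate", "nonwhite_share")]
        ).iloc[0]
        assert out["slope"] > 0


class TestConcentration:
    def test_all_members_in_one_practice(self):
        recs = _grouped_records()
        recs["practice_key"] = 3
        rep = concentration_report(recs, pd.Series(True, index=recs.index), 1)
        assert rep["share_in_top"] == 1.0

    def test_uniform_spread_gives_n_over_m(self):
        recs = _grouped_records(400, 0, 0)
        recs["practice_key"] = np.arange(400) % 8
        rep = concentration_report(recs, pd.Series(True, index=recs.index), 2)
        assert np.isclose(rep["share_in_top"], 2 / 8)

    def test_shares_nondecreasing_in_top_n(self):
        recs = _grouped_records(seed=9)
        mask = pd.Series(True, index=recs.index)
        shares = [
            concentration_report(recs, mask, t)["share_in_top"] for t in (1, 3, 5, 10)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(shares, shares[1:]))

    def test_empty_pattern_rejected(self):
        recs = _grouped_records()
        with pytest.raises(UndefinedRateError):
            concentration_report(recs, pd.Series(False, index=recs.index), 1)


def test_zero_multiracial_screen_flags_large_practices():
    n = 3000
    recs = pd.DataFrame(
        {
            "person_key": np.arange(n),
            "practice_key": np.repeat([0, 1], [1500, 1500]),
            "ehr_races": ["White"] * 1500 + ["Multiracial[White+Black]"] * 1500,
            "ehr_category": ["White"] * 1500 + ["Multiracial"] * 1500,
            "census_races": ["Multiracial[White+Black]"] * n,
            "census_category": ["Multiracial"] * n,
        }
    )
    out = zero_multiracial_practices(recs, min_patients=1000)
    assert list(out["practice_key"]) == [0]
    assert out.iloc[0]["n_single_vs_census_multiracial"] == 1500
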