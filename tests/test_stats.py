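"""Endpoint adjudication and the survival/agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mibgquant.phantom import make_cohort
from mibgquant.stats import (
    adjudicate,
    agreement_band,
    bellshape_test,
    categorize_late_hm,
    compare_groups,
    cox_fit,
    icc,
    km_curve,
    summarize_by_group,
    td_roc,
)


class TestAdjudicate:
    def test_single_scd_record(self):
        df = pd.DataFrame(
            [{"event_type": "SCD", "event_month": 12.0, "followup_months": 12.0}]
        )
        out = adjudicate(df)
        assert bool(out.ae_flag.iloc[0]) is True
        assert bool(out.icd_therapy_flag.iloc[0]) is False
        assert out.ae_time.iloc[0] == 12.0

    def test_fixture_composition_totals(self, endpoint_fixture_cohort):
        out = adjudicate(endpoint_fixture_cohort)
        assert int(out.ae_flag.sum()) == 69
        assert int(out.icd_therapy_flag.sum()) == 22
        # secondary endpoint is a subset of the composite
        assert (out.icd_therapy_flag <= out.ae_flag).all()
        per_type = out[out.ae_flag].event_type.value_counts()
        assert int(out.ae_flag.sum()) == int(per_type.sum())

    def test_all_censored(self):
        df = pd.DataFrame(
            {"event_type": ["none"] * 5, "event_month": [np.nan] * 5,
             "followup_months": [10.0, 20, 30, 40, 50]}
        )
        out = adjudicate(df)
        assert not out.ae_flag.any()
        assert (out.ae_time == out.followup_months).all()

    def test_event_without_month_errors(self):
        df = pd.DataFrame(
            [{"event_type": "SCD", "event_month": np.nan, "followup_months": 10.0}]
        )
        with pytest.raises(ValueError):
            adjudicate(df)

    def test_unknown_event_type_errors(self):
        df = pd.DataFrame(
            [{"event_type": "stroke", "event_month": 3.0, "followup_months": 10.0}]
        )
        with pytest.raises(ValueError):
            adjudicate(df)


class TestCompareGroups:
    def test_identical_groups_t_test_p_one(self):
        vals = np.array([55.0, 60.1, 62.3, 58.7, 61.0, 57.2, 59.9, 63.4])
        df = pd.DataFrame(
            {"x": np.concatenate([vals, vals]),
             "g": [True] * len(vals) + [False] * len(vals)}
        )
        res = compare_groups(df, "x", "g")
        assert res.test == "t-test"
        assert res.p_value > 0.99

    def test_perfectly_separated_2x2(self):
        df = pd.DataFrame({"x": [True] * 10 + [False] * 10,
                           "g": [True] * 10 + [False] * 10})
        res = compare_groups(df, "x", "g")
        assert res.test in ("chi2", "fisher")
        assert res.p_value < 0.001

    def test_skewed_data_uses_mann_whitney(self):
        rng = np.random.default_rng(0)
        a = np.exp(rng.normal(0.0, 1.0, 120))
        b = np.exp(rng.normal(0.8, 1.0, 120))
        df = pd.DataFrame({"x": np.concatenate([a, b]),
                           "g": [True] * 120 + [False] * 120})
        res = compare_groups(df, "x", "g")
        assert res.test == "mann-whitney"
        assert res.p_value < 1e-4

    def test_hazard_linked_marker_differs_between_event_groups(self):
        df = adjudicate(make_cohort(seed=11, n=5000))
        res = compare_groups(df, "ess", "ae_flag")
        assert res.p_value < 0.01

    def test_constant_variable_errors(self):
        df = pd.DataFrame({"x": [1.0] * 10, "g": [True] * 5 + [False] * 5})
        with pytest.raises(ValueError):
            compare_groups(df, "x", "g")

    def test_summary_table_shape(self):
        df = adjudicate(make_cohort(seed=1, n=400))
        table = summarize_by_group(df, ["age", "sex_male", "ess"], "ae_flag")
        assert list(table.index) == ["age", "sex_male", "ess"]
        assert {"all", "with_event", "without_event", "p_value"} <= set(table.columns)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        res = km_curve([5.0, 10.0, 15.0], [False, False, False])
        assert np.all(res.survival == 1.0)

    def test_hand_product_limit_two_subjects(self):
        res = km_curve([1.0, 2.0], [True, True])
        assert res.survival_at(1.0) == pytest.approx(0.5)
        assert res.survival_at(2.0) == pytest.approx(0.0)
        assert res.survival_at(0.5) == pytest.approx(1.0)

    def test_hand_product_limit_with_censoring(self):
        # events at 1 (n=4) and 3 (n=2 at risk): S = 3/4, then 3/8
        res = km_curve([1.0, 2.0, 3.0, 4.0], [True, False, True, False])
        assert res.survival_at(1.5) == pytest.approx(0.75)
        assert res.survival_at(3.5) == pytest.approx(0.375)

    def test_censoring_time_after_last_event_is_irrelevant(self):
        a = km_curve([1.0, 2.0, 9.0], [True, True, False])
        b = km_curve([1.0, 2.0, 99.0], [True, True, False])
        assert a.survival_at(2.0) == b.survival_at(2.0)
        assert b.survival_at(50.0) == b.survival_at(2.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0, 2.0], [True, True])


class TestCox:
    def test_null_covariate_recovers_unit_hazard_ratio(self):
        df = adjudicate(make_cohort(seed=21, n=4000))
        rng = np.random.default_rng(0)
        df["noise"] = rng.normal(size=len(df))
        fit = cox_fit(df, "ae_time", "ae_flag", ["noise"])
        lo, hi = fit.ci("noise")
        assert lo < 1.0 < hi
        assert abs(fit.hr("noise") - 1.0) < 0.1

    def test_sequential_change_chi2_is_loglik_gain(self):
        df = adjudicate(make_cohort(seed=22, n=3000))
        fit_seq = cox_fit(df, "ae_time", "ae_flag", ["ess", "lvef"], sequential=True)
        fit_first = cox_fit(df, "ae_time", "ae_flag", ["ess"])
        fit_full = cox_fit(df, "ae_time", "ae_flag", ["ess", "lvef"])
        expected = 2.0 * (fit_full.log_likelihood - fit_first.log_likelihood)
        assert fit_seq.summary.loc["lvef", "change_chi2"] == pytest.approx(expected, abs=1e-8)
        assert fit_seq.summary.loc["ess", "change_chi2"] == pytest.approx(
            fit_first.model_chi2, abs=1e-8
        )
        assert fit_seq.model_chi2 >= 0.0

    def test_ph_check_reported(self):
        df = adjudicate(make_cohort(seed=23, n=2000))
        fit = cox_fit(df, "ae_time", "ae_flag", ["ess"])
        assert "ess" in fit.ph_pvalues.index
        assert isinstance(fit.ph_ok, bool)

    def test_min_events_guard(self):
        df = adjudicate(make_cohort(seed=24, n=200))
        few = pd.concat([df[df.ae_flag].head(3), df[~df.ae_flag]])
        with pytest.raises(ValueError):
            cox_fit(few, "ae_time", "ae_flag", ["ess"])

    def test_constant_covariate_rejected(self):
        df = adjudicate(make_cohort(seed=25, n=500))
        df["flat"] = 1.0
        with pytest.raises(ValueError):
            cox_fit(df, "ae_time", "ae_flag", ["flat"])


class TestTdRoc:
    def test_independent_marker_auc_near_half(self):
        df = adjudicate(make_cohort(seed=31, n=2000))
        rng = np.random.default_rng(1)
        res = td_roc(df.ae_time, df.ae_flag, rng.normal(size=len(df)), horizon=24.0)
        assert abs(res.auc - 0.5) < 0.05

    def test_perfect_marker_auc_one(self):
        rng = np.random.default_rng(2)
        times = rng.uniform(1.0, 48.0, 300)
        events = np.ones(300, dtype=bool)  # no censoring
        marker = (times <= 24.0).astype(float)
        res = td_roc(times, events, marker, horizon=24.0)
        assert res.auc == pytest.approx(1.0, abs=1e-12)

    def test_reduces_to_plain_roc_without_censoring(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        n = 250
        marker = rng.normal(size=n)
        times = rng.exponential(20.0 / np.exp(0.5 * marker))
        events = np.ones(n, dtype=bool)
        horizon = 15.0
        res = td_roc(times, events, marker, horizon=horizon)
        plain = roc_auc_score((times <= horizon).astype(int), marker)
        assert res.auc == pytest.approx(plain, abs=1e-9)

    def test_no_events_before_horizon_errors(self):
        with pytest.raises(ValueError):
            td_roc([30.0, 40.0], [True, True], [1.0, 2.0], horizon=10.0)


class TestHmCategories:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.2, "intermediate"), (1.6, "intermediate"), (1.19, "low"),
         (1.61, "high"), (0.9, "low"), (2.5, "high")],
    )
    def test_boundary_policy(self, value, expected):
        assert categorize_late_hm(value) == expected

    @given(v=st.floats(min_value=0.01, max_value=10.0))
    def test_partition_of_positive_reals(self, v):
        assert categorize_late_hm(v) in ("low", "intermediate", "high")

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            categorize_late_hm(0.0)
        with pytest.raises(ValueError):
            categorize_late_hm(-1.3)

    def test_fixture_vector_counts(self, hm_fixture_values):
        cats = categorize_late_hm(hm_fixture_values)
        assert (cats == "low").sum() == 8
        assert (cats == "high").sum() == 51
        assert (cats == "intermediate").sum() == 111

    def test_bellshape_null_not_significant(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"late_hm": rng.uniform(0.9, 2.2, 600), "flag": rng.binomial(1, 0.4, 600) == 1}
        )
        res = bellshape_test(df, "flag")
        assert res.p_value > 0.05

    def test_bellshape_detects_intermediate_excess(self):
        rng = np.random.default_rng(5)
        hm = rng.uniform(0.9, 2.2, 800)
        cats = categorize_late_hm(hm)
        p = np.where(cats == "intermediate", 0.55, 0.25)
        df = pd.DataFrame({"late_hm": hm, "flag": rng.binomial(1, p) == 1})
        res = bellshape_test(df, "flag")
        assert res.p_value < 0.001
        assert res.table.shape == (2, 2)


class TestIcc:
    def test_identical_readers_perfect_agreement(self):
        col = np.array([10.0, 14, 9, 22, 17, 30, 25, 12])
        res = icc(np.column_stack([col, col, col]))
        assert res.value == pytest.approx(1.0, abs=1e-9)
        assert res.band == "excellent"

    def test_independent_noise_poor_agreement(self):
        rng = np.random.default_rng(6)
        res = icc(rng.normal(size=(400, 3)))
        assert abs(res.value) < 0.15
        assert res.band == "poor"

    def test_matches_variance_component_closed_form(self):
        # subjects N(0, 4), independent errors N(0, 1): ICC = 4/5
        rng = np.random.default_rng(7)
        subj = rng.normal(0.0, 2.0, size=(500, 1))
        table = 30.0 + subj + rng.normal(0.0, 1.0, size=(500, 3))
        res = icc(table)
        assert res.value == pytest.approx(0.8, abs=0.02)
        assert res.ci_lower < res.value < res.ci_upper

    def test_band_thresholds(self):
        assert agreement_band(0.39) == "poor"
        assert agreement_band(0.40) == "fair"
        assert agreement_band(0.60) == "good"
        assert agreement_band(0.75) == "excellent"
        assert agreement_band(0.846) == "excellent"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((10, 3)))  # zero between-subject variance
        with pytest.raises(ValueError):
            icc(np.random.default_rng(0).normal(size=(4, 3)))  # too few subjects
        with pytest.raises(ValueError):
            icc(np.random.default_rng(0).normal(size=(10, 1)))  # one reader
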