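"""Contingency/predictive values, KM, log-rank, Cox, ROC and baseline table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import auc_pair_count_oracle, chi2_2x2_oracle, km_oracle, logrank_oracle
from spectscore.prognosis import (
    ContingencyTable,
    EventClass,
    SoftEventPolicy,
    baseline_table,
    chi2_increment,
    combine_flags,
    cox_fit,
    delong_compare,
    km_estimate,
    logrank_test,
    make_contingency,
    pearson_chi2_2x2,
    predictive_values,
    roc_auc,
    survival_arrays,
    validate_cohort,
)
from spectscore.synthetic import CohortSpec, simulate_cohort


def cohort_from_counts(flag_event, flag_noevent, n_event, n_noevent, hard_events=0):
    """Minimal cohort with given abnormal-flag counts in each outcome group."""
    rows = []
    for i in range(n_event):
        ev = "hard" if i < hard_events else "soft"
        rows.append(dict(event=ev, flag=i < flag_event))
    for i in range(n_noevent):
        rows.append(dict(event="none", flag=i < flag_noevent))
    df = pd.DataFrame(rows)
    for col in ["age", "lvef", "sss", "srs", "sds", "sbs"]:
        df[col] = 50.0
    for col in ["sex", "dm", "htn", "dyslipidemia", "smoking", "uap", "ace", "bb", "ccb"]:
        df[col] = 0
    df["id"] = [f"P{i}" for i in range(len(df))]
    df["followup_days"] = 1000.0
    return df


class TestContingencyAndPredictiveValues:
    def test_counts_from_event_rates(self):
        # 10/29 events abnormal and 18/122 non-events abnormal
        df = cohort_from_counts(10, 18, 29, 122)
        t = make_contingency(df, df["flag"].to_numpy(), EventClass.ALL)
        assert (t.tp, t.fn, t.fp, t.tn) == (10, 19, 18, 104)
        pv = predictive_values(t)
        assert pv.npv == pytest.approx(100 * 104 / 123)

    def test_all_normal_no_events(self):
        df = cohort_from_counts(0, 0, 0, 10)
        t = make_contingency(df, df["flag"].to_numpy())
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 0, 10)
        pv = predictive_values(t)
        assert pv.npv == 100.0 and pv.ppv is None

    def test_hard_event_class_counts_hard_only(self):
        df = cohort_from_counts(4, 17, 7, 144, hard_events=7)
        t = make_contingency(df, df["flag"].to_numpy(), EventClass.HARD)
        assert (t.tp, t.fn, t.fp, t.tn) == (4, 3, 17, 127)
        assert predictive_values(t).npv_rounded == 98

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty"):
            make_contingency(pd.DataFrame(columns=["event"]), np.array([]))

    @settings(max_examples=100, derandomize=True)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50), tn=st.integers(1, 50))
    def test_ppv_npv_exact_identities(self, tp, fp, fn, tn):
        """PPV x (TP+FP) == 100 x TP before rounding (and same for NPV)."""
        pv = predictive_values(ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn))
        if pv.ppv is not None:
            assert pv.ppv * (tp + fp) == pytest.approx(100.0 * tp)
        assert pv.npv * (tn + fn) == pytest.approx(100.0 * tn)


class TestCombineFlags:
    @pytest.mark.parametrize(
        "a,b,mode,expected",
        [(True, False, "OR", True), (True, False, "AND", False),
         (True, True, "AND", True), (False, False, "OR", False)],
    )
    def test_truth_table(self, a, b, mode, expected):
        assert combine_flags(a, b, mode) is expected

    def test_or_flag_never_less_sensitive_than_either_alone(self):
        """OR-combination sensitivity >= each single flag, by 2x2 enumeration."""
        rng = np.random.default_rng(7)
        events = rng.random(60) < 0.3
        fa = rng.random(60) < 0.4
        fb = rng.random(60) < 0.4
        if not events.any():
            events[0] = True
        sens = lambda f: (f & events).sum() / events.sum()
        combined = combine_flags(fa, fb, "OR")
        assert sens(combined) >= max(sens(fa), sens(fb))
        assert combine_flags(fa, fb, "AND").sum() <= min(fa.sum(), fb.sum())


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = km_estimate([5.0, 10.0, 20.0], [False, False, False])
        assert np.all(km.survival == 1.0)

    def test_single_event_quarter_drop(self):
        km = km_estimate([10.0, 12.0, 15.0, 20.0], [True, False, False, False])
        assert km.survival_at(10.0) == pytest.approx(0.75)
        assert km.survival_at(9.9) == 1.0

    def test_matches_hand_product_limit_with_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.integers(1, 40, size=20).astype(float)
        events = rng.random(20) < 0.6
        km = km_estimate(times, events)
        t_oracle, s_oracle = km_oracle(times, events)
        for t, s in zip(t_oracle, s_oracle):
            assert km.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_uncensored_km_equals_empirical_survival(self):
        times = np.array([3.0, 5.0, 5.0, 8.0, 12.0])
        km = km_estimate(times, np.ones(5, bool))
        for t in [2, 3, 5, 8, 12]:
            assert km.survival_at(t) == pytest.approx((times > t).mean())

    def test_negative_time_raises(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1.0, 5.0], [True, False])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [5.0, 10.0, 15.0, 20.0]
        e = [True, False, True, False]
        chi2, p = logrank_test((t, e), (t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_no_events_gives_p_one(self):
        chi2, p = logrank_test(([5.0, 8.0], [False, False]), ([3.0, 9.0], [False, False]))
        assert chi2 == 0.0 and p == 1.0

    def test_matches_risk_table_oracle(self):
        rng = np.random.default_rng(11)
        ta = rng.integers(1, 50, 25).astype(float)
        ea = rng.random(25) < 0.5
        tb = rng.integers(1, 50, 30).astype(float)
        eb = rng.random(30) < 0.7
        chi2, _ = logrank_test((ta, ea), (tb, eb))
        assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-6)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(20, 15), rng.exponential(10, 18)
        ea, eb = rng.random(15) < 0.6, rng.random(18) < 0.6
        s1, p1 = logrank_test((ta, ea), (tb, eb))
        s2, p2 = logrank_test((tb, eb), (ta, ea))
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_test(([], []), ([5.0], [True]))


class TestCox:
    def test_null_covariate_hr_near_one(self):
        """Covariate independent of hazard: 95% CI covers 1 in most replicates."""
        covered = 0
        for seed in range(21, 26):
            df = simulate_cohort(CohortSpec(n=1500, log_hr={}, baseline_hazard=1e-4, seed=seed))
            lo, hi = cox_fit(df, ["smoking"]).ci("smoking")
            covered += lo < 1.0 < hi
        assert covered >= 4

    def test_collinear_covariates_rejected(self):
        df = simulate_cohort(CohortSpec(n=200, seed=1))
        df["dm2"] = df["dm"]
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(df, ["dm", "dm2"])

    def test_constant_covariate_rejected(self):
        df = simulate_cohort(CohortSpec(n=200, seed=1))
        df["const"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["const"])

    def test_no_events_rejected(self):
        df = simulate_cohort(CohortSpec(n=50, seed=2))
        df["event"] = "none"
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, ["dm"])

    def test_binary_covariate_bias_shrinks_with_n(self):
        """Log-HR recovery improves from n=200 to n=2000 (exponential baseline)."""
        true_log_hr = float(np.log(3.0))
        bias = {}
        for n in (200, 2000):
            errs = []
            for seed in range(8):
                df = simulate_cohort(
                    CohortSpec(n=n, dm_prev=0.3, log_hr={"dm": true_log_hr},
                               baseline_hazard=1e-4, seed=100 + seed)
                )
                fit = cox_fit(df, ["dm"])
                errs.append(float(np.log(fit.hazard_ratio("dm"))) - true_log_hr)
            bias[n] = abs(np.mean(errs))
        assert bias[2000] < bias[200]
        assert bias[2000] < 0.1

    def test_hard_event_policies(self):
        df = simulate_cohort(CohortSpec(n=400, seed=9))
        d1, e1, k1 = survival_arrays(df, EventClass.HARD, SoftEventPolicy.CENSOR_AT_SOFT)
        d2, e2, k2 = survival_arrays(df, EventClass.HARD, SoftEventPolicy.DROP_SOFT)
        n_soft = (df["event"] == "soft").sum()
        assert k1.sum() == len(df) and k2.sum() == len(df) - n_soft
        assert e1.sum() == e2.sum() == (df["event"] == "hard").sum()


class TestChi2Increment:
    def test_adding_prognostic_score_increases_chi2(self):
        # score with HR 1.2 per point; clinical base model of dm + lvef
        df = simulate_cohort(
            CohortSpec(n=500, log_hr={"dm": float(np.log(2.0)), "sss": float(np.log(1.2))}, seed=42)
        )
        base = cox_fit(df, ["dm", "lvef"])
        full = cox_fit(df, ["dm", "lvef", "sss"])
        delta, p = chi2_increment(base, full)
        assert delta > 0
        assert p < 0.05

    def test_identical_models_delta_zero(self):
        df = simulate_cohort(CohortSpec(n=300, seed=5))
        fit = cox_fit(df, ["dm"])
        delta, p = chi2_increment(fit, fit)
        assert delta == 0.0 and p == 1.0

    def test_non_nested_models_rejected(self):
        df = simulate_cohort(CohortSpec(n=300, seed=5))
        a = cox_fit(df, ["dm"])
        b = cox_fit(df, ["lvef"])
        with pytest.raises(ValueError, match="nest"):
            chi2_increment(a, b)

    def test_null_covariate_adds_negligible_chi2(self):
        df = simulate_cohort(CohortSpec(n=800, log_hr={"dm": float(np.log(3.0))}, seed=13))
        base = cox_fit(df, ["dm"])
        full = cox_fit(df, ["dm", "dyslipidemia"])
        delta, p = chi2_increment(base, full)
        assert delta < 4.0  # ~chi2(1) noise, no real signal
        assert p > 0.01


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [False, False, False, True, True, True])
        assert r.auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.3
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        scores = rng.integers(0, 10, 50).astype(float)  # many ties
        labels = rng.random(50) < 0.4
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_pair_count_oracle(scores, labels), abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [True, True])

    def test_delong_identical_scores_p_one(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=80)
        labels = rng.random(80) < 0.4
        auc_a, auc_b, z, p = delong_compare(s, s, labels)
        assert auc_a == auc_b and p == 1.0

    def test_delong_detects_better_score(self):
        rng = np.random.default_rng(3)
        labels = rng.random(400) < 0.5
        good = labels + rng.normal(0, 0.5, 400)
        bad = rng.normal(size=400)
        auc_a, auc_b, z, p = delong_compare(good, bad, labels)
        assert auc_a > auc_b
        assert p < 0.001


class TestBaselineTable:
    def test_chi2_matches_closed_form(self):
        assert pearson_chi2_2x2(12, 9, 17, 113)[0] == pytest.approx(
            chi2_2x2_oracle(12, 9, 17, 113), rel=1e-12
        )

    def test_structure_and_event_fraction(self):
        df = simulate_cohort(CohortSpec(n=300, seed=17))
        table = baseline_table(df, EventClass.ALL)
        assert "dm" in table.index and "sss_ge4" in table.index
        event = df["event"] != "none"
        expected_pct = 100 * ((df["sss"] >= 4) & event).sum() / event.sum()
        assert table.loc["sss_ge4", "event_sd"] == pytest.approx(expected_pct)

    def test_identical_groups_give_p_one_for_balanced_categoricals(self):
        df = cohort_from_counts(5, 5, 10, 10)
        df["dm"] = ([1] * 5 + [0] * 5) * 2
        table = baseline_table(df, EventClass.ALL)
        assert table.loc["dm", "p"] == pytest.approx(1.0)

    def test_validate_cohort_catches_schema_errors(self):
        df = simulate_cohort(CohortSpec(n=20, seed=1))
        validate_cohort(df)  # passes
        with pytest.raises(ValueError, match="missing columns"):
            validate_cohort(df.drop(columns=["lvef"]))
        bad = df.copy()
        bad.loc[0, "event"] = "unknown"
        with pytest.raises(ValueError, match="invalid event"):
            validate_cohort(bad)
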