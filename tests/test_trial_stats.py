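"""Trial statistics: ANCOVA, mixed model, rmANOVAs, learning, FDR, NNT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from efpnf import published, trial

import statsim


class TestReductionDelta:
    def test_test_group_printed_reduction(self):
        assert trial.reduction_delta(40.52, 31.66) == pytest.approx(8.86)

    def test_control_group_printed_reduction(self):
        assert trial.reduction_delta(43.06, 39.78) == pytest.approx(3.28)

    def test_no_change(self):
        assert trial.reduction_delta(17.3, 17.3) == 0.0


class TestAncova:
    def test_post_equals_pre_absorbed_by_covariate(self):
        table = statsim.ancova_frame(rng=np.random.default_rng(0))
        wide = table.pivot_table(index=["subject_id", "group"],
                                 columns="timepoint", values="score").reset_index()
        rows = []
        for _, r in wide.iterrows():
            for tp in ("pre", "post"):
                rows.append({"subject_id": r.subject_id, "group": r.group,
                             "timepoint": tp, "instrument": "CAPS5",
                             "score": r.pre, "diagnosis": None})
        res = trial.ancova_immediate(pd.DataFrame(rows))
        assert res.F == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_partial_eta_identity(self):
        table = statsim.ancova_frame(gap=5.0, rng=np.random.default_rng(1))
        res = trial.ancova_immediate(table)
        df1, df2 = res.df
        expected = res.F * df1 / (res.F * df1 + df2)
        assert res.partial_eta_sq == pytest.approx(expected, abs=1e-9)

    def test_small_group_rejected(self):
        table = statsim.ancova_frame(n1=2, n2=10, rng=np.random.default_rng(2))
        with pytest.raises(ValueError, match="fewer than 3"):
            trial.ancova_immediate(table)

    def test_rejection_rate_matches_noncentral_f_power(self):
        # fixed design (same covariate values every repetition) so the
        # noncentrality is exact: lambda = gap^2 / (sigma^2 c) with c the
        # group entry of (X'X)^{-1}
        rng = np.random.default_rng(3)
        n1 = n2 = 15
        gap, sd = 8.0, 8.0
        pre = 40.0 + 9.0 * rng.standard_normal(n1 + n2)
        X = np.column_stack([np.ones(n1 + n2), pre,
                             (np.arange(n1 + n2) < n1).astype(float)])
        c = np.linalg.inv(X.T @ X)[2, 2]
        lam = gap**2 / (sd**2 * c)
        df2 = n1 + n2 - 3
        crit = stats.f.isf(0.05, 1, df2)
        analytic = stats.ncf.sf(crit, 1, df2, lam)
        reps, rej = 4000, 0
        for _ in range(reps):
            table = statsim.ancova_frame(n1=n1, n2=n2, gap=gap, sd=sd,
                                         rng=rng, pre=pre)
            rej += trial.ancova_immediate(table).p < 0.05
        assert abs(rej / reps - analytic) < 0.03


class TestMixedModel:
    def test_compound_symmetry_equals_random_intercept_loglik(self):
        table = statsim.longitudinal_frame(rng=np.random.default_rng(4))
        res = trial.mixed_model_followup(table, "PCL5")
        oracle = statsim.cs_reml_loglik(table, "PCL5")
        assert abs(res.loglik_reml - oracle) < 1e-6

    def test_reduces_to_ols_without_subject_effect(self):
        # zero between-subject variance: the CS REML criterion at the
        # boundary equals the fixed-effects REML log-likelihood
        table = statsim.longitudinal_frame(s_b=0.0, n1=150, n2=150,
                                           rng=np.random.default_rng(6))
        res = trial.mixed_model_followup(table, "PCL5")
        sub = table.copy()
        sub["time"] = sub["timepoint"].map(trial.TIME_CODES)
        sub["grp"] = (sub["group"] == "test").astype(float)
        X = np.column_stack([np.ones(len(sub)), sub["grp"], sub["time"],
                             sub["grp"] * sub["time"]])
        y = sub["score"].to_numpy()
        n, p = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        s2 = rss / (n - p)
        ols_reml = -0.5 * (n * np.log(s2) + np.linalg.slogdet(X.T @ X)[1]
                           - p * np.log(s2) + (n - p)
                           + (n - p) * np.log(2 * np.pi))
        assert res.sigma2_between < 1e-4 * res.sigma2_within
        assert abs(res.loglik_reml - ols_reml) < 1e-4

    def test_interaction_estimate_unbiased(self):
        # short parameter-recovery check; the full-scale version runs in
        # the acceptance suite
        rng = np.random.default_rng(6)
        truth = 1.0
        ests = []
        for _ in range(60):
            table = statsim.longitudinal_frame(n1=40, n2=15, interaction=truth,
                                               rng=rng)
            res = trial.mixed_model_followup(table, "PCL5")
            ests.append(res.fixed_effects["group_x_time"]["coef"])
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth) < 3 * se

    def test_insufficient_followup_rejected(self):
        table = statsim.longitudinal_frame(rng=np.random.default_rng(7))
        pre_only = table[table.timepoint == "pre"]
        with pytest.raises(ValueError, match="80%"):
            trial.mixed_model_followup(pre_only, "PCL5")

    def test_categorical_time_sensitivity_runs(self):
        table = statsim.longitudinal_frame(rng=np.random.default_rng(8))
        res = trial.mixed_model_followup(table, "PCL5",
                                         time_coding="categorical")
        assert res.converged
        assert any("grp" in k or "group" in k for k in res.fixed_effects)


class TestRmAnovaConditionSession:
    def test_two_level_reduction_equals_squared_paired_t(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((12, 2, 1))
        res = trial.rm_anova_condition_session(x)
        t, p = stats.ttest_rel(x[:, 0, 0], x[:, 1, 0])
        assert res["condition"]["F"] == pytest.approx(t**2, abs=1e-9)
        assert res["condition"]["p"] == pytest.approx(p, abs=1e-9)

    def test_location_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((10, 2, 10))
        a = trial.rm_anova_condition_session(x)
        b = trial.rm_anova_condition_session(x + 100.0)
        for eff in ("condition", "session", "condition_x_session"):
            assert a[eff]["F"] == pytest.approx(b[eff]["F"], rel=1e-9)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        x = rng.standard_normal((8, 2, 4))
        res = trial.rm_anova_condition_session(x)
        rows = []
        for s in range(8):
            for ci, cond in enumerate(["Watch", "Regulate"]):
                for sess in range(4):
                    rows.append({"subject": s, "condition": cond,
                                 "session": sess, "value": x[s, ci, sess]})
        df = pd.DataFrame(rows)
        tab = pg.rm_anova(data=df, dv="value", within=["condition", "session"],
                          subject="subject", detailed=True)
        f_cond = float(tab.loc[tab.Source == "condition", "F"].iloc[0])
        f_int = float(tab.loc[tab.Source == "condition * session", "F"].iloc[0])
        assert res["condition"]["F"] == pytest.approx(f_cond, rel=1e-9)
        assert res["condition_x_session"]["F"] == pytest.approx(f_int, rel=1e-9)

    def test_incomplete_subjects_dropped_and_counted(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((6, 2, 3))
        x[0, 1, 2] = np.nan
        res = trial.rm_anova_condition_session(x)
        assert res.n_subjects == 5 and res.n_dropped == 1


class TestSplitPlotGroupTime:
    def test_null_data_moderate_f(self):
        table = statsim.longitudinal_frame(rng=np.random.default_rng(13))
        res = trial.rm_anova_group_time(table, "PCL5")
        assert res.n_subjects == 40
        for eff in ("group", "time", "group_x_time"):
            assert np.isfinite(res[eff]["F"])

    def test_detects_interaction(self):
        table = statsim.longitudinal_frame(interaction=-3.0, s_w=2.0,
                                           rng=np.random.default_rng(14))
        res = trial.rm_anova_group_time(table, "PCL5")
        assert res["group_x_time"]["p"] < 0.01


class TestPairedLearningTest:
    def test_identical_halves_null(self):
        arr = np.tile(np.linspace(-1, -0.5, 5), (4, 2))
        res = trial.paired_learning_test(arr)
        assert res.t == 0.0 and res.p == 1.0 and not res.degenerate

    def test_constant_difference_degenerate(self):
        arr = np.hstack([np.zeros((10, 5)), -np.ones((10, 5))])
        res = trial.paired_learning_test(arr)
        assert res.degenerate

    def test_missing_half_excluded_and_reported(self):
        rng = np.random.default_rng(15)
        arr = rng.standard_normal((6, 10))
        arr[0, 5:] = np.nan
        res = trial.paired_learning_test(arr)
        assert res.n == 5 and res.n_excluded == 1

    def test_learning_cohort_detected(self):
        from efpnf.synthetic import AgentParams
        succ = statsim.session_success_cohort(AgentParams(), 30, seed=16)
        res = trial.paired_learning_test(succ)
        assert res.p < 0.05
        assert res.mean_last5 < res.mean_first5


class TestBhFdr:
    def test_step_up_hand_example(self):
        adj = trial.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert trial.bh_fdr([0.33])[0] == pytest.approx(0.33)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = trial.bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            trial.bh_fdr([0.1, 1.2])


class TestArrNnt:
    def test_simple_counts(self):
        res = trial.arr_and_nnt(20, 40, 0, 15)
        assert res.arr == pytest.approx(0.5)
        assert res.nnt == pytest.approx(2.0)

    def test_printed_arr_reciprocal(self):
        assert trial.nnt_from_arr(published.ARR) == pytest.approx(4.0486, abs=1e-3)
        assert abs(round(trial.nnt_from_arr(published.ARR), 2) - published.NNT) <= 0.01

    def test_equal_proportions_flagged(self):
        res = trial.arr_and_nnt(5, 20, 5, 20)
        assert not res.beneficial and np.isnan(res.nnt)

    def test_newcombe_interval_brackets_estimate(self):
        res = trial.arr_and_nnt(24, 40, 2, 15)
        lo, hi = res.ci_arr
        assert lo < res.arr < hi
        assert res.ci_nnt is not None
        assert res.ci_nnt[0] < res.nnt < res.ci_nnt[1]

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            trial.arr_and_nnt(50, 40, 0, 15)

    def test_nnt_from_arr_examples(self):
        assert trial.nnt_from_arr(0.5) == 2.0
        assert trial.nnt_from_arr(0.25) == 4.0
        with pytest.raises(ValueError):
            trial.nnt_from_arr(0.0)


class TestPowerUtility:
    def test_reported_design_in_plausible_range(self):
        n = trial.required_sample_size(published.POWER_ETA_SQ,
                                       published.POWER_ALPHA,
                                       published.POWER_TARGET)
        assert 42 <= n <= 45


class TestAnalyzeTrial:
    def test_bundle_contains_all_blocks(self):
        from efpnf.synthetic import AgentParams, CohortParams, generate_clinical_cohort
        table, _ = generate_clinical_cohort(CohortParams(), seed=17)
        succ = statsim.session_success_cohort(AgentParams(), 10, seed=18)
        result = trial.analyze_trial(table, session_success=succ)
        assert set(result) == {"ancova", "nnt", "mixed_model", "per_protocol",
                               "learning"}
        assert result["learning"] is not None
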