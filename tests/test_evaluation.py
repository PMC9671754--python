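"""Diagnostic-accuracy statistics against independent oracles.

Cross-checks: brute-force pair counting for AUC, a stratified bootstrap for
the DeLong variance, statsmodels' exact binomial interval for
Clopper–Pearson, closed-form binomial tails for McNemar.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from widqec.evaluation import (
    ConfusionMatrix,
    clopper_pearson,
    confusion,
    delong_test,
    mcnemar_exact,
    predictive_value_curve,
    predictive_values,
    roc_auc,
    round_percent,
    sensitivity_specificity,
    stratified_performance,
    summarize,
    time_stratified_sensitivity,
)


def brute_force_auc(cases, controls):
    wins = sum(
        1.0 if x > y else 0.5 if x == y else 0.0
        for x in cases for y in controls
    )
    return wins / (len(cases) * len(controls))


class TestConfusion:
    def test_all_correct(self):
        pred = ["positive"] * 5 + ["negative"] * 5
        truth = ["case"] * 5 + ["control"] * 5
        cm = confusion(pred, truth)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (5, 0, 5, 0)

    def test_symptomatic_smear_cohort_counts(self):
        # 71 cases of which 69 test positive; 66 controls of which 16 do
        pred = (["positive"] * 69 + ["negative"] * 2
                + ["positive"] * 16 + ["negative"] * 50)
        truth = ["case"] * 71 + ["control"] * 66
        cm = confusion(pred, truth)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (69, 16, 50, 2)

    def test_empty_input_all_zero(self):
        cm = confusion([], [])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (0, 0, 0, 0)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["yes"], ["case"])


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "cm, sens_pct, spec_pct",
        [
            (ConfusionMatrix(69, 16, 50, 2), 97.2, 75.8),   # cervical smear
            (ConfusionMatrix(118, 16, 104, 13), 90.1, 86.7),  # self-collected
            (ConfusionMatrix(8, 6, 49, 0), 100.0, 89.1),    # vaginal swab
        ],
    )
    def test_cohort_level_points_round_to_one_decimal(self, cm, sens_pct,
                                                      spec_pct):
        sens, spec = sensitivity_specificity(cm)
        assert round_percent(sens) == sens_pct
        assert round_percent(spec) == spec_pct

    def test_no_cases_undefined(self):
        with pytest.raises(ValueError, match="sensitivity undefined"):
            sensitivity_specificity(ConfusionMatrix(0, 0, 10, 0))


class TestClopperPearson:
    def test_perfect_detection_lower_bound(self):
        lo, hi = clopper_pearson(8, 8)
        assert round_percent(lo) == 63.1
        assert hi == 1.0

    def test_zero_successes_lower_is_zero(self):
        lo, _ = clopper_pearson(0, 10)
        assert lo == 0.0

    def test_near_one_interval(self):
        lo, hi = clopper_pearson(20, 22)
        assert (round(lo, 3), round(hi, 3)) == (0.708, 0.989)

    def test_successes_above_n_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)

    @given(n=st.integers(1, 200), frac=st.floats(0, 1))
    def test_matches_statsmodels_beta_method(self, n, frac):
        k = min(n, int(round(frac * n)))
        lo, hi = clopper_pearson(k, n)
        sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(0.0 if k == 0 else sm_lo, abs=1e-12)
        assert hi == pytest.approx(1.0 if k == n else sm_hi, abs=1e-12)

    def test_coverage_is_conservative(self):
        # exact intervals over-cover: simulate the control-arm binomial
        rng = np.random.default_rng(2024)
        n, p = 66, 0.76
        covered = 0
        draws = rng.binomial(n, p, size=2000)
        for k in draws:
            lo, hi = clopper_pearson(int(k), n)
            covered += lo <= p <= hi
        assert covered / 2000 >= 0.95


class TestPredictiveValues:
    def test_symptomatic_prevalence_point(self):
        ppv, npv = predictive_values(69 / 71, 50 / 66, 0.09)
        assert round_percent(ppv, 0) == 28.0
        assert round_percent(npv, 0) == 100.0

    def test_perfect_specificity_gives_ppv_one(self):
        assert predictive_values(0.8, 1.0, 0.2)[0] == 1.0

    def test_zero_prevalence_gives_npv_one(self):
        assert predictive_values(0.8, 0.9, 0.0)[1] == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            predictive_values(1.2, 0.5, 0.1)

    def test_curve_single_point_matches_scalar(self):
        curve = predictive_value_curve(69 / 71, 50 / 66, [0.09])
        ppv, npv = predictive_values(69 / 71, 50 / 66, 0.09)
        assert curve["ppv"].iloc[0] == pytest.approx(ppv)
        assert curve["npv"].iloc[0] == pytest.approx(npv)

    def test_uninformative_test_ppv_equals_prevalence(self):
        grid = [0.05, 0.25, 0.6]
        curve = predictive_value_curve(0.5, 0.5, grid)
        np.testing.assert_allclose(curve["ppv"], grid)

    @given(s=st.floats(0.01, 0.99), sp=st.floats(0.01, 0.99))
    def test_ppv_rises_npv_falls_with_prevalence(self, s, sp):
        grid = np.linspace(0.02, 0.9, 12)
        curve = predictive_value_curve(s, sp, grid)
        assert (np.diff(curve["ppv"]) > 0).all()
        assert (np.diff(curve["npv"]) < 0).all()


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([3, 4, 1, 2], ["case", "case", "control", "control"])
        assert res.auc == 1.0

    def test_all_ties_give_half(self):
        res = roc_auc([5, 5, 5, 5], ["case", "case", "control", "control"])
        assert res.auc == 0.5

    def test_small_example_pair_count(self):
        res = roc_auc([3, 5, 1, 4], ["case", "case", "control", "control"])
        assert res.auc == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], ["case", "case"])

    def test_curve_anchored_and_monotone(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=30)
        truth = np.where(rng.random(30) < 0.5, "case", "control")
        if len(set(truth)) < 2:
            truth[0], truth[1] = "case", "control"
        res = roc_auc(scores, truth)
        curve = res.curve
        assert tuple(curve[0]) == (0.0, 0.0) and tuple(curve[-1]) == (1.0, 1.0)
        assert (np.diff(curve[:, 0]) >= 0).all()
        assert (np.diff(curve[:, 1]) >= 0).all()
        assert np.trapezoid(curve[:, 1], curve[:, 0]) == pytest.approx(res.auc)

    def test_matches_brute_force_and_sklearn_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n1 = rng.integers(2, 16)
            n0 = rng.integers(2, 16)
            # ties likely: scores drawn from a small integer support
            cases = rng.integers(0, 8, size=n1).astype(float)
            controls = rng.integers(0, 8, size=n0).astype(float)
            scores = np.concatenate([cases, controls])
            truth = np.array(["case"] * n1 + ["control"] * n0)
            mine = roc_auc(scores, truth).auc
            assert mine == pytest.approx(brute_force_auc(cases, controls))
            assert mine == pytest.approx(
                roc_auc_score((truth == "case").astype(int), scores)
            )


def bootstrap_var_delta_auc(scores_a, scores_b, truth, n_boot, seed):
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(truth == "case")
    ctrl_idx = np.flatnonzero(truth == "control")
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        ci = rng.choice(case_idx, size=len(case_idx), replace=True)
        ki = rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True)
        idx = np.concatenate([ci, ki])
        t = truth[idx]
        deltas[i] = (roc_auc(scores_a[idx], t).auc
                     - roc_auc(scores_b[idx], t).auc)
    return deltas.var(ddof=1)


class TestDeLong:
    def _toy(self, seed=99, n=40):
        rng = np.random.default_rng(seed)
        truth = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
        signal = (truth == "case").astype(float)
        a = signal * 1.2 + rng.normal(size=n)
        b = 0.6 * a + rng.normal(size=n)  # correlated, weaker modality
        return a, b, truth

    def test_self_comparison_is_null(self):
        a, _, truth = self._toy()
        res = delong_test(a, a, truth)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_swapping_modalities_negates_z(self):
        a, b, truth = self._toy()
        fwd = delong_test(a, b, truth)
        rev = delong_test(b, a, truth)
        assert rev.z == pytest.approx(-fwd.z)
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_aucs_match_roc_module(self):
        a, b, truth = self._toy()
        res = delong_test(a, b, truth)
        assert res.auc_a == pytest.approx(roc_auc(a, truth).auc)
        assert res.auc_b == pytest.approx(roc_auc(b, truth).auc)

    @pytest.mark.parametrize("seed", [99, 7])
    def test_variance_agrees_with_stratified_bootstrap(self, seed):
        a, b, truth = self._toy(seed=seed)
        res = delong_test(a, b, truth)
        boot = bootstrap_var_delta_auc(a, b, truth, n_boot=2000, seed=seed + 1)
        assert res.var_diff == pytest.approx(boot, rel=0.2)

    def test_degenerate_unequal_aucs_signalled(self):
        truth = np.array(["case", "case", "control", "control"])
        a = np.array([2.0, 2.0, 1.0, 1.0])
        b = np.array([1.0, 1.0, 2.0, 2.0])
        with pytest.raises(ZeroDivisionError):
            delong_test(a, b, truth)


class TestMcNemar:
    def test_one_sided_discordance_closed_form(self):
        a = ["positive"] * 10 + ["negative"] * 5
        b = ["negative"] * 10 + ["negative"] * 5
        assert mcnemar_exact(a, b) == pytest.approx(2 * 0.5**10)

    def test_balanced_discordance_capped_at_one(self):
        a = ["positive", "positive", "negative", "negative"]
        b = ["negative", "negative", "positive", "positive"]
        assert mcnemar_exact(a, b) == 1.0

    def test_no_discordant_pairs(self):
        a = ["positive", "negative"]
        assert mcnemar_exact(a, a) == 1.0

    @given(b=st.integers(0, 12), c=st.integers(0, 12))
    def test_matches_binomial_tail_sum(self, b, c):
        a_vec = (["positive"] * b + ["negative"] * c + ["positive"] * 3)
        b_vec = (["negative"] * b + ["positive"] * c + ["positive"] * 3)
        n = b + c
        if n == 0:
            expected = 1.0
        else:
            m = min(b, c)
            tail = sum(math.comb(n, k) for k in range(m + 1)) * 0.5**n
            expected = min(1.0, 2 * tail)
        assert mcnemar_exact(a_vec, b_vec) == pytest.approx(expected)


class TestSummaries:
    def test_summary_reproduces_component_statistics(self):
        cm = ConfusionMatrix(69, 16, 50, 2)
        s = summarize(cm, prevalence=0.09)
        assert round_percent(s.sensitivity) == 97.2
        assert round_percent(s.sens_ci[0]) == 90.2
        assert round_percent(s.sens_ci[1]) == 99.7
        assert round_percent(s.spec_ci[0]) == 63.6
        assert round_percent(s.spec_ci[1]) == 85.5
        assert s.sens_ci[0] <= s.sensitivity <= s.sens_ci[1]

    def test_single_stratum_equals_overall(self):
        pred = np.array(["positive"] * 6 + ["negative"] * 6)
        truth = np.array(["case"] * 6 + ["control"] * 6)
        overall = summarize(confusion(pred, truth))
        strata = stratified_performance(pred, truth, ["all"] * 12)
        assert strata["all"].sensitivity == overall.sensitivity
        assert strata["all"].spec_ci == overall.spec_ci

    def test_strata_counts_partition(self):
        rng = np.random.default_rng(1)
        n = 60
        truth = np.where(rng.random(n) < 0.4, "case", "control")
        pred = np.where(rng.random(n) < 0.5, "positive", "negative")
        strata = rng.choice(["pre", "post"], size=n)
        out = stratified_performance(pred, truth, strata)
        total_cases = sum(s.n_cases for s in out.values())
        total_controls = sum(s.n_controls for s in out.values())
        assert total_cases == (truth == "case").sum()
        assert total_controls == (truth == "control").sum()

    def test_equal_effect_strata_have_overlapping_cis(self):
        # same detection probability in both strata: intervals must overlap
        rng = np.random.default_rng(5)
        n = 200
        truth = np.array(["case"] * 100 + ["control"] * 100)
        pred = np.where(
            truth == "case",
            np.where(rng.random(n) < 0.9, "positive", "negative"),
            np.where(rng.random(n) < 0.15, "positive", "negative"),
        )
        strata = rng.choice(["pre", "post"], size=n)
        out = stratified_performance(pred, truth, strata)
        lo = max(out["pre"].sens_ci[0], out["post"].sens_ci[0])
        hi = min(out["pre"].sens_ci[1], out["post"].sens_ci[1])
        assert lo <= hi


class TestTimeStratified:
    def test_lead_time_split_reproduces_group_rates(self):
        # 22 short-lead cases with 20 detected; 10 long-lead with 2
        pred = np.array(
            ["positive"] * 20 + ["negative"] * 2
            + ["positive"] * 2 + ["negative"] * 8
        )
        truth = np.array(["case"] * 32)
        months = np.array([6.0] * 22 + [24.0] * 10)
        res = time_stratified_sensitivity(pred, truth, months)
        assert res["lt_cutpoint"]["sensitivity"] == pytest.approx(20 / 22)
        assert round_percent(res["lt_cutpoint"]["sensitivity"]) == 90.9
        assert res["ge_cutpoint"]["sensitivity"] == pytest.approx(0.2)
        assert round_percent(res["lt_cutpoint"]["ci"][0]) == 70.8
        assert round_percent(res["lt_cutpoint"]["ci"][1]) == 98.9
        assert res["fisher_p"] < 0.05

    def test_all_cases_short_lead_equals_overall(self):
        pred = np.array(["positive"] * 9 + ["negative"])
        truth = np.array(["case"] * 10)
        months = np.full(10, 3.0)
        res = time_stratified_sensitivity(pred, truth, months)
        assert res["lt_cutpoint"]["sensitivity"] == pytest.approx(0.9)
        assert math.isnan(res["ge_cutpoint"]["sensitivity"])

    def test_cutpoint_beyond_data_leaves_late_group_empty(self):
        pred = np.array(["positive"] * 4)
        truth = np.array(["case"] * 4)
        months = np.array([1.0, 2.0, 3.0, 4.0])
        res = time_stratified_sensitivity(pred, truth, months,
                                          cutpoint_months=120.0)
        assert res["ge_cutpoint"]["n_cases"] == 0
        assert math.isnan(res["ge_cutpoint"]["sensitivity"])

    def test_missing_case_months_rejected(self):
        with pytest.raises(ValueError, match="months_to_event"):
            time_stratified_sensitivity(
                np.array(["positive"]), np.array(["case"]),
                np.array([np.nan]),
            )
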