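"""AUC/DeLong machinery, confusion metrics, chi-square comparison,
predictive values, and covariate balance tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpanel import (
    SampleTable,
    auc_with_delong,
    baseline_balance_tests,
    compare_accuracy_chi2,
    confusion_at_cutoff,
    delong_paired_test,
    predictive_values,
)

from .conftest import simple_samples


def pairwise_auc(case, control):
    """Exhaustive psi-mean oracle: 1 / 0.5 / 0 per case-control pair."""
    total = 0.0
    for x in case:
        for y in control:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(case) * len(control))


class TestAUC:
    def test_small_example_seven_ninths(self):
        r = auc_with_delong(np.array([2.0, 3, 4]), np.array([1.0, 2, 3]))
        assert r.auc == pytest.approx(7 / 9)

    def test_matches_exhaustive_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            m = int(rng.integers(2, 20))
            n = int(rng.integers(2, 20))
            case = np.round(rng.normal(size=m), 1)  # rounding forces ties
            control = np.round(rng.normal(size=n), 1)
            r = auc_with_delong(case, control)
            assert r.auc == pytest.approx(pairwise_auc(case, control), abs=1e-12)

    def test_complete_separation(self):
        r = auc_with_delong(np.array([3.0, 4, 5]), np.array([0.0, 1, 2]))
        assert r.auc == 1.0
        assert r.variance == 0.0
        assert r.auc_ci == (1.0, 1.0)

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(1)
        case, control = rng.normal(1, 1, 8), rng.normal(size=10)
        a = auc_with_delong(case, control).auc
        b = auc_with_delong(-case, -control).auc
        assert a + b == pytest.approx(1.0)

    def test_curve_endpoints_monotone_and_area_matches(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            case = np.round(rng.normal(0.5, 1, int(rng.integers(3, 25))), 1)
            control = np.round(rng.normal(size=int(rng.integers(3, 25))), 1)
            r = auc_with_delong(case, control)
            assert tuple(r.curve[0]) == (0.0, 0.0)
            assert tuple(r.curve[-1]) == (1.0, 1.0)
            assert (np.diff(r.curve[:, 0]) >= 0).all()
            assert (np.diff(r.curve[:, 1]) >= 0).all()
            area = np.trapezoid(r.curve[:, 1], r.curve[:, 0])
            assert abs(area - r.auc) < 1e-12

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            auc_with_delong(np.array([]), np.array([1.0]))


class TestDeLongPaired:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        y = np.array([True] * 15 + [False] * 15)
        auc_a, auc_b, z, p = delong_paired_test(s, s, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_monotone_transform_rank_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=40)
        y = np.array([True] * 20 + [False] * 20)
        s[y] += 0.8
        auc_a, auc_b, z, p = delong_paired_test(s, np.exp(s / 2) + 3, y)
        assert auc_a == pytest.approx(auc_b)
        assert p == 1.0

    def test_agrees_with_paired_bootstrap(self):
        """n = 30 paired instance: normal-theory p within 0.05 of a
        10,000-rep stratified paired-bootstrap AUC-difference test."""
        rng = np.random.default_rng(5)
        y = np.array([True] * 15 + [False] * 15)
        a = rng.normal(size=30) + 1.1 * y
        b = 0.6 * a + rng.normal(scale=0.8, size=30) + 0.4 * y
        _, _, _, p = delong_paired_test(a, b, y)
        case_idx = np.flatnonzero(y)
        ctl_idx = np.flatnonzero(~y)
        diffs = np.empty(10_000)
        for r in range(10_000):
            ci = rng.choice(case_idx, len(case_idx), replace=True)
            ki = rng.choice(ctl_idx, len(ctl_idx), replace=True)
            da = auc_with_delong(a[ci], a[ki]).auc
            db = auc_with_delong(b[ci], b[ki]).auc
            diffs[r] = da - db
        frac = (diffs <= 0).mean()
        p_boot = 2 * min(frac, 1 - frac)
        assert abs(p - p_boot) < 0.05

    def test_variance_close_to_bootstrap_variance(self):
        """DeLong AUC variance within 15% of the 10,000-rep bootstrap
        variance at n >= 50 per class (5 seeds)."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            case = rng.normal(0.9, 1, 60)
            control = rng.normal(size=60)
            r = auc_with_delong(case, control)
            boot = np.empty(10_000)
            for i in range(10_000):
                boot[i] = auc_with_delong(
                    rng.choice(case, 60), rng.choice(control, 60)
                ).auc
            assert r.variance == pytest.approx(boot.var(ddof=1), rel=0.15)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            delong_paired_test(np.zeros(3), np.zeros(4), np.array([1, 0, 1], bool))


class TestConfusionMetrics:
    def test_published_wald_ci_for_sensitivity(self):
        """0.983 at n = 708 gives the printed 95% CI (0.974-0.993)."""
        # 696 of 708 cases called positive
        scores = np.concatenate([np.ones(696), -np.ones(12), -np.ones(10)])
        labels = np.array([True] * 708 + [False] * 10)
        cm = confusion_at_cutoff(scores, labels)
        assert round(cm.sensitivity, 3) == 0.983
        lo, hi = cm.sensitivity_ci
        assert round(lo, 3) == 0.974
        assert round(hi, 3) == 0.993

    def test_all_correct_clips_upper_ci(self):
        scores = np.array([1.0, 1, -1, -1])
        labels = np.array([True, True, False, False])
        cm = confusion_at_cutoff(scores, labels)
        assert cm.accuracy == 1.0
        assert cm.accuracy_ci == (1.0, 1.0)

    def test_accuracy_from_integer_counts(self):
        # tp=696 fn=13 tn=693 fp=16 -> accuracy 1389/1417
        scores = np.concatenate(
            [np.ones(696), -np.ones(13), -np.ones(693), np.ones(16)]
        )
        labels = np.array([True] * 709 + [False] * 709)
        cm = confusion_at_cutoff(scores, labels)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (696, 13, 693, 16)
        assert cm.accuracy == pytest.approx(1389 / 1418)

    def test_tie_at_cutoff_is_positive(self):
        cm = confusion_at_cutoff(
            np.array([0.0, -0.1]), np.array([True, False]), cutoff=0.0
        )
        assert cm.tp == 1 and cm.tn == 1


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        chi2, p = compare_accuracy_chi2(90, 100, 90, 100)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        chi2, p = compare_accuracy_chi2(90, 100, 70, 100)
        assert chi2 == pytest.approx(12.5)
        assert p == pytest.approx(stats.chi2.sf(12.5, 1), abs=1e-12)
        assert 0.0003 < p < 0.0005

    def test_symmetric_in_models(self):
        a = compare_accuracy_chi2(80, 100, 60, 90)
        b = compare_accuracy_chi2(60, 90, 80, 100)
        assert a == b

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="margin"):
            chi2, p = compare_accuracy_chi2(100, 100, 50, 50)
        assert p == 1.0


class TestPredictiveValues:
    def test_perfect_test(self):
        assert predictive_values(1.0, 1.0, 0.3) == (1.0, 1.0)

    def test_published_screening_ppv(self):
        ppv, npv = predictive_values(706 / 709, 675 / 708, 0.00742)
        assert round(ppv, 3) == 0.138
        assert round(npv, 2) == 1.00

    def test_hand_arithmetic(self):
        ppv, _ = predictive_values(0.8, 0.9, 0.5)
        assert ppv == pytest.approx(8 / 9)

    def test_uninformative_test_identity(self):
        # sens = 1 - spec: post-test equals pre-test probability
        for p in (0.1, 0.42, 0.9):
            ppv, npv = predictive_values(0.7, 0.3, p)
            assert ppv == pytest.approx(p)
            assert npv == pytest.approx(1 - p)

    def test_undefined_flagged(self):
        with pytest.warns(UserWarning, match="PPV undefined"):
            ppv, npv = predictive_values(0.0, 1.0, 0.5)
        assert np.isnan(ppv)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            predictive_values(1.2, 0.5, 0.1)


class TestBaselineBalance:
    def test_identical_tables_give_p_one(self):
        t = simple_samples([True] * 10 + [False] * 10)
        res = baseline_balance_tests(t, t)
        assert all(p == pytest.approx(1.0) for p in res.values())

    def test_equal_stage_proportions_give_p_one(self):
        """Stage composition 95.2/4.1/0.7% in both arms: chi-square p = 1."""
        def arm():
            t = simple_samples([True] * 708)
            t.df["stage"] = ["IA"] * 674 + ["IB"] * 29 + ["II"] * 5
            return t

        res = baseline_balance_tests(arm(), arm())
        assert res["stage"] == pytest.approx(1.0)

    def test_type_one_error_rate_under_null(self):
        """Two cohorts from the same config: few rejections at 0.05."""
        from mirpanel import SimulationConfig, generate_cohort

        rejections = 0
        for seed in range(4):
            _, a = generate_cohort(SimulationConfig(seed=200 + seed))
            _, b = generate_cohort(SimulationConfig(seed=300 + seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = baseline_balance_tests(a, b)
            rejections += sum(p < 0.05 for p in res.values())
        assert rejections <= 3
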