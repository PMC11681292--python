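"""Threshold selection, alert classification, net benefit, decision curves,
incidence standardisation and the bootstrap curve comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shiftmon import (
    CohortConfig,
    DegenerateDataError,
    InvalidTargetError,
    classify_alert,
    compare_decision_curves,
    confusion_summary,
    decision_curve,
    generate_cohort,
    net_benefit,
    select_threshold,
    standardize_incidence,
)
from shiftmon.decision import _positives_to_add

from conftest import brute_force_threshold


class TestSelectThreshold:
    def test_separable_case_smallest_candidate(self):
        # any t in (0.2, 0.8] is perfect; smallest candidate there is 0.8
        assert select_threshold([0.8, 0.9, 0.1, 0.2], [1, 1, 0, 0]) == 0.8

    def test_exhaustive_scan_example(self):
        # candidate 0.6: FPR=1/3, FNR=0 -> 1/3; candidate 0.7: FPR=1/3,
        # FNR=1/2 -> 1/6, the minimum over the full candidate scan
        probs = [0.1, 0.2, 0.6, 0.7, 0.9]
        labels = [0, 0, 1, 0, 1]
        assert select_threshold(probs, labels) == 0.7

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            select_threshold([0.2, 0.8], [1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.sampled_from([round(0.05 * k, 2) for k in range(1, 20)]),
                      st.integers(0, 1)),
            min_size=2,
            max_size=200,
        ).filter(lambda xs: 0 < sum(y for _, y in xs) < len(xs))
    )
    def test_matches_brute_force_scan(self, xs):
        probs = np.array([p for p, _ in xs])
        labels = np.array([y for _, y in xs])
        assert select_threshold(probs, labels) == brute_force_threshold(probs, labels)


class TestClassifyAlert:
    @pytest.mark.parametrize(
        "label, alerted, onset, alert_time, expected",
        [
            (0, False, None, None, "TN"),
            (0, True, None, None, "FP"),
            (1, False, 5.0, None, "FN"),
            (1, True, 5.0, 2.0, "TP"),  # alert strictly before onset
            (1, True, None, None, "TP"),  # onset unknown: alert any time counts
            (1, True, 5.0, 6.0, "TP_AFTER_ONSET"),
            (1, True, 5.0, 5.0, "TP_AFTER_ONSET"),  # not strictly before
        ],
    )
    def test_five_categories(self, label, alerted, onset, alert_time, expected):
        assert classify_alert(label, alerted, onset, alert_time) == expected

    def test_onset_on_control_is_inconsistent(self):
        with pytest.raises(DegenerateDataError):
            classify_alert(0, True, onset_time=3.0)

    def test_alerted_case_with_onset_needs_alert_time(self):
        with pytest.raises(DegenerateDataError):
            classify_alert(1, True, onset_time=3.0, alert_time=None)


class TestConfusionSummary:
    def test_threshold_zero_alerts_everyone(self):
        cs = confusion_summary([0.3, 0.6, 0.1], [1, 0, 1], 0.0)
        assert cs.alert_rate == 1.0 and cs.fnr == 0.0

    def test_threshold_one_alerts_nobody(self):
        cs = confusion_summary([0.3, 0.6, 0.1], [1, 0, 1], 1.0)
        assert cs.alert_rate == 0.0 and cs.fpr == 0.0

    def test_hand_enumeration(self):
        cs = confusion_summary([0.9, 0.4, 0.5, 0.2, 0.4], [1, 1, 0, 0, 0], 0.5)
        assert (cs.tp, cs.fn, cs.fp, cs.tn) == (1, 1, 1, 2)
        assert cs.alert_rate == pytest.approx(0.4)
        assert cs.fpr == pytest.approx(1 / 3)
        assert cs.fnr == pytest.approx(0.5)


class TestNetBenefit:
    def test_zero_threshold_gives_tp_rate(self):
        assert net_benefit(7, 13, 100, 0.0) == pytest.approx(0.07)

    def test_worked_example(self):
        assert net_benefit(10, 20, 100, 0.2) == pytest.approx(0.05, abs=1e-12)

    def test_treat_all_is_zero_at_prevalence(self):
        pi = 0.3
        n = 1000
        tp, fp = pi * n, (1 - pi) * n
        assert net_benefit(tp, fp, n, pi) == pytest.approx(0.0, abs=1e-12)

    def test_threshold_one_is_undefined(self):
        with pytest.raises(InvalidTargetError):
            net_benefit(1, 1, 10, 1.0)


class TestDecisionCurve:
    def test_perfect_classifier_plateau_at_prevalence(self):
        probs = np.r_[np.full(30, 0.9), np.full(70, 0.1)]
        labels = np.r_[np.ones(30), np.zeros(70)].astype(int)
        curve = decision_curve(probs, labels, thresholds=np.arange(0.0, 0.9, 0.01))
        pi = 0.3
        below = curve.thresholds <= 0.1
        above = (curve.thresholds > 0.1) & (curve.thresholds < 0.9)
        np.testing.assert_allclose(curve.nb_model[above], pi, atol=1e-12)
        assert curve.nb_model[0] == pytest.approx(pi)  # p_t = 0: alert everyone
        assert (curve.nb_model[below] <= pi + 1e-12).all()

    def test_reference_strategies(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 400)
        labels[:2] = [0, 1]
        curve = decision_curve(rng.random(400), labels)
        assert (curve.nb_none == 0).all()
        pi = labels.mean()
        # treat-all crosses zero exactly at the prevalence
        np.testing.assert_allclose(
            curve.nb_all, pi - (1 - pi) * curve.thresholds / (1 - curve.thresholds)
        )
        assert (curve.nb_model <= pi + 1e-12).all()

    def test_uninformative_calibrated_model_tracks_envelope(self):
        rng = np.random.default_rng(4)
        n, pi = 50_000, 0.2
        labels = (rng.random(n) < pi).astype(int)
        probs = np.clip(rng.normal(pi, 0.01, n), 0.001, 0.999)  # no information
        curve = decision_curve(probs, labels, thresholds=np.arange(0.0, 0.5, 0.01))
        envelope = np.maximum(curve.nb_all, 0.0)
        away = np.abs(curve.thresholds - pi) > 0.05  # noisy only near prevalence
        np.testing.assert_allclose(curve.nb_model[away], envelope[away], atol=0.01)

    def test_empty_grid(self):
        with pytest.raises(InvalidTargetError):
            decision_curve([0.5], [1], thresholds=[])


class TestStandardizeIncidence:
    def test_equal_incidence_unchanged(self):
        from shiftmon import ScoredCohort

        rng = np.random.default_rng(21)
        frames = []
        for period in ("a", "b"):
            frames.append(
                pd.DataFrame(
                    {
                        "case_id": [f"{period}-{i}" for i in range(100)],
                        "period": period,
                        "label": np.r_[np.ones(10), np.zeros(90)].astype(int),
                        "raw_score": rng.uniform(0.05, 0.95, 100),
                        "true_prob": np.nan,
                        "onset_time": np.nan,
                        "los": np.nan,
                        "split": "test",
                    }
                )
            )
        cohort = ScoredCohort(pd.concat(frames, ignore_index=True))
        out = standardize_incidence(cohort, seed=0)
        pd.testing.assert_frame_equal(out.frame, cohort.frame)

    def test_worked_duplicate_count(self):
        # 20 positives among 1,000, target 3%: k=10 beats k=11
        assert _positives_to_add(20, 1000, 0.03) == 10

    def test_only_adds_duplicated_positives(self):
        cohort = generate_cohort(
            CohortConfig(periods=("a", "b"), n_per_period=2000,
                         incidence=(0.05, 0.20), seed=22)
        )
        out = standardize_incidence(cohort, seed=1)
        n = cohort.n
        pd.testing.assert_frame_equal(out.frame.iloc[:n], cohort.frame)  # originals intact
        added = out.frame.iloc[n:]
        assert (added["label"] == 1).all()
        # every added row is a verbatim copy of an existing positive
        merged = added.merge(cohort.frame, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_curves_start_at_common_incidence(self):
        cohort = generate_cohort(
            CohortConfig(periods=("a", "b"), n_per_period=5000,
                         incidence=(0.05, 0.20), seed=23)
        )
        out = standardize_incidence(cohort, seed=1)
        target = max(cohort.incidence(p) for p in cohort.periods)
        for p in out.periods:
            split = out.test(p)
            curve = decision_curve(split["raw_score"], split["label"], thresholds=[0.0])
            assert curve.nb_model[0] == pytest.approx(target, abs=2.0 / len(split))


class TestCompareDecisionCurves:
    def test_identical_splits_large_p(self):
        cohort = generate_cohort(CohortConfig(periods=("a",), n_per_period=3000, seed=30))
        split = cohort.test("a")
        probs = split["raw_score"].to_numpy()
        labels = split["label"].to_numpy()
        comp = compare_decision_curves(probs, labels, probs, labels, n_boot=2000, seed=0)
        assert all(p > 0.5 for p in comp.p_values)

    def test_discrimination_drift_detected_at_mid_thresholds(self):
        strong = generate_cohort(
            CohortConfig(periods=("a",), n_per_period=5000, mu_pos=2.0, seed=31)
        )
        weak = generate_cohort(
            CohortConfig(periods=("b",), n_per_period=5000, mu_pos=0.5, seed=32)
        )
        sa, sb = strong.test("a"), weak.test("b")
        comp = compare_decision_curves(
            sa["true_prob"].to_numpy(), sa["label"].to_numpy(),
            sb["true_prob"].to_numpy(), sb["label"].to_numpy(),
            n_boot=1000, seed=0,
        )
        by_threshold = dict(zip(comp.thresholds, comp.p_values))
        assert all(by_threshold[t] < 0.05 for t in (0.05, 0.10, 0.15, 0.20))

    def test_n_boot_floor(self):
        with pytest.raises(DegenerateDataError):
            compare_decision_curves([0.5, 0.6], [0, 1], [0.5, 0.6], [0, 1], n_boot=10)

    def test_type_one_error_near_nominal(self):
        """Null study: two independent periods from one generator; per-threshold
        rejection rate at alpha=.05 over 1,000 replicate studies stays in
        [0.03, 0.07]."""
        n_studies = 1000
        rejections = np.zeros(6)
        for run in range(n_studies):
            cohort = generate_cohort(
                CohortConfig(periods=("a", "b"), n_per_period=600, seed=20_000 + run)
            )
            sa, sb = cohort.test("a"), cohort.test("b")
            comp = compare_decision_curves(
                sa["true_prob"].to_numpy(), sa["label"].to_numpy(),
                sb["true_prob"].to_numpy(), sb["label"].to_numpy(),
                n_boot=200, seed=run,
            )
            rejections += np.array(comp.p_values) < 0.05
        rates = rejections / n_studies
        assert ((0.03 <= rates) & (rates <= 0.07)).all(), rates
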