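"""Weighted metrics: rank-sum AUROC, PR curve, lifted variants, calibration,
decision curves, sensitivity thresholds, and alarm silencing."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from sepsiseval import (
    EvaluationSample,
    Trajectory,
    UndefinedMetricError,
    UnreachableTargetError,
    alarm_rates,
    brier,
    calibrate_isotonic_cv,
    decision_curve,
    lifted_metrics,
    pr_curve_metrics,
    precision_at_recall,
    threshold_at_sensitivity,
    weighted_auroc,
)


def make_sample(y_pred, y_true, weights=None, stay_ids=None):
    y_pred = np.asarray(y_pred, dtype=float)
    n = y_pred.size
    return EvaluationSample(
        stay_ids=np.asarray(
            stay_ids if stay_ids is not None else [f"s{i}" for i in range(n)],
            dtype=object,
        ),
        bins=np.full(n, np.nan),
        y_pred=y_pred,
        y_true=np.asarray(y_true, dtype=int),
        weights=np.asarray(
            weights if weights is not None else np.ones(n), dtype=float
        ),
    )


def auroc_pairwise_oracle(sample):
    """Brute-force weighted P(pos > neg) + 0.5 P(tie) over all pairs."""
    pos = sample.y_true == 1
    num = den = 0.0
    for sp, wp in zip(sample.y_pred[pos], sample.weights[pos]):
        for sn, wn in zip(sample.y_pred[~pos], sample.weights[~pos]):
            num += wp * wn * (1.0 if sp > sn else 0.5 if sp == sn else 0.0)
            den += wp * wn
    return num / den


class TestWeightedAuroc:
    def test_perfect_separation(self):
        s = make_sample([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert weighted_auroc(s).value == 1.0

    def test_all_ties_give_half(self):
        s = make_sample([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert weighted_auroc(s).value == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            weighted_auroc(make_sample([0.1, 0.2], [1, 1]))

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 31))
            s = make_sample(
                rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n),
                np.r_[1, 0, rng.integers(0, 2, n - 2)],
                rng.uniform(0.1, 3.0, n),
            )
            assert abs(weighted_auroc(s).value - auroc_pairwise_oracle(s)) < 1e-12

    def test_agrees_with_sklearn(self, rng):
        """Independent cross-check against the reference ROC implementation."""
        for _ in range(20):
            n = 50
            s = make_sample(
                rng.uniform(0, 1, n),
                np.r_[1, 0, rng.integers(0, 2, n - 2)],
                rng.uniform(0.5, 2.0, n),
            )
            ref = roc_auc_score(s.y_true, s.y_pred, sample_weight=s.weights)
            assert abs(weighted_auroc(s).value - ref) < 1e-10

    def test_prevalence_invariance(self, rng):
        """Duplicating every negative at half weight leaves AUROC unchanged."""
        n = 40
        s = make_sample(
            rng.uniform(0, 1, n), np.r_[1, 0, rng.integers(0, 2, n - 2)]
        )
        neg = s.y_true == 0
        dup = make_sample(
            np.r_[s.y_pred, s.y_pred[neg]],
            np.r_[s.y_true, s.y_true[neg]],
            np.r_[np.where(neg, 0.5, 1.0), np.full(neg.sum(), 0.5)],
        )
        assert abs(weighted_auroc(s).value - weighted_auroc(dup).value) < 1e-12


class TestPrCurve:
    def test_perfect_separation_interior_threshold(self):
        s = make_sample([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        m = pr_curve_metrics(s, threshold=0.5)
        assert m["ppv"].value == 1.0
        assert m["npv"].value == 1.0
        assert m["recall"].value == 1.0
        assert m["auprc"].value == 1.0

    def test_interpolated_precision_midpoint(self):
        # operating points (recall, precision) = (0.5, 1.0) and (1.0, 0.6):
        # positives {0.9, 0.8}; thresholding below 0.8 brings in 2 of 3 negatives
        s = make_sample(
            [0.9, 0.8, 0.8, 0.8, 0.1], [1, 0, 1, 0, 0],
            [1.0, 2 / 3, 1.0, 2 / 3, 1.0],
        )
        _, prec, rec = __import__(
            "sepsiseval.metrics", fromlist=["_pr_operating_points"]
        )._pr_operating_points(s)
        np.testing.assert_allclose(rec[:2], [0.5, 1.0])
        np.testing.assert_allclose(prec[:2], [1.0, 0.6])
        assert abs(precision_at_recall(s, 0.75) - 0.8) < 1e-12

    def test_null_auprc_near_prevalence(self, rng):
        n = 10_000
        s = make_sample(rng.uniform(0, 1, n), rng.random(n) < 0.2)
        assert abs(pr_curve_metrics(s)["auprc"].value - s.prevalence) < 0.02

    def test_auprc_agrees_with_sklearn_average_precision(self, rng):
        for _ in range(10):
            n = 200
            s = make_sample(
                rng.uniform(0, 1, n),
                np.r_[1, 0, rng.integers(0, 2, n - 2)],
                rng.uniform(0.5, 2.0, n),
            )
            ref = average_precision_score(
                s.y_true, s.y_pred, sample_weight=s.weights
            )
            assert abs(pr_curve_metrics(s)["auprc"].value - ref) < 1e-10


class TestLiftedMetrics:
    def test_perfect_classifier_lift_is_inverse_prevalence(self):
        y = np.r_[np.ones(10), np.zeros(90)]
        s = make_sample(np.r_[np.linspace(0.8, 0.9, 10), np.linspace(0.1, 0.2, 90)], y)
        m = lifted_metrics(s, threshold=0.5)
        assert m["lifted_ppv"].value == pytest.approx(10.0)
        assert m["lifted_auprc"].value == pytest.approx(10.0)
        assert m["recall_at_2prev"].value == 1.0

    def test_null_lifted_auprc_near_one(self, rng):
        n = 10_000
        s = make_sample(rng.uniform(0, 1, n), rng.random(n) < 0.1)
        assert lifted_metrics(s)["lifted_auprc"].value == pytest.approx(1.0, abs=0.2)

    def test_unreached_precision_flagged(self):
        # anti-informative scores: precision never reaches 2x prevalence
        s = make_sample([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        m = lifted_metrics(s)
        assert m["recall_at_2prev"].value == 0.0
        assert m["recall_at_2prev"].flag == "precision_2prev_unreached"


class TestBrier:
    def test_closed_forms(self):
        assert brier(make_sample([1.0, 0.0], [1, 0])).value == 0.0
        assert brier(make_sample([0.5] * 4, [1, 0, 0, 1])).value == 0.25
        # constant p on labels with prevalence q -> p^2 (1-q) + (1-p)^2 q
        p, q = 0.3, 0.25
        s = make_sample([p] * 8, [1, 0, 0, 0] * 2)
        assert brier(s).value == pytest.approx(p**2 * (1 - q) + (1 - p) ** 2 * q)


class TestIsotonicCalibration:
    def _sample(self, rng, n=4000, invert=False):
        true_p = rng.uniform(0.05, 0.95, n)
        y = (rng.random(n) < true_p).astype(int)
        score = 1.0 - true_p if invert else true_p
        return make_sample(score, y)

    def test_calibrated_sample_brier_stable(self, rng):
        s = self._sample(rng)
        cal, _ = calibrate_isotonic_cv(s, seed=0)
        assert abs(brier(cal).value - brier(s).value) < 0.005

    def test_anticalibrated_scores_improved(self, rng):
        s = self._sample(rng, invert=True)
        cal, _ = calibrate_isotonic_cv(s, seed=0)
        assert brier(cal).value <= brier(s).value

    def test_monotone_map_preserves_ranking(self, rng):
        s = self._sample(rng, n=2000)
        cal, _ = calibrate_isotonic_cv(s, seed=0)
        # ties introduced by pooling can only move AUROC marginally
        assert weighted_auroc(cal).value == pytest.approx(
            weighted_auroc(s).value, abs=0.02
        )

    def test_too_few_stays_rejected(self):
        with pytest.raises(UndefinedMetricError):
            calibrate_isotonic_cv(make_sample([0.1, 0.9], [0, 1]), folds=5)


class TestDecisionCurve:
    def test_net_benefit_closed_form(self):
        # TP=30, FP=10, N=100 at p_t=0.5 -> NB = 0.30 - 0.10 = 0.20
        y_pred = np.r_[np.full(30, 0.9), np.full(10, 0.9), np.full(60, 0.1)]
        y_true = np.r_[np.ones(30), np.zeros(10), np.zeros(55), np.ones(5)]
        dc = decision_curve(make_sample(y_pred, y_true), thresholds=[0.5])
        assert dc.net_benefit[0] == pytest.approx(0.20)
        assert np.all(dc.treat_none == 0.0)
        prev = 0.35
        assert dc.treat_all[0] == pytest.approx(prev - (1 - prev) * 1.0)

    def test_model_never_beats_prevalence(self, rng):
        n = 2000
        s = make_sample(rng.uniform(0, 1, n), rng.random(n) < 0.3)
        dc = decision_curve(s)
        assert np.all(dc.net_benefit <= dc.prevalence + 1e-12)


class TestThresholdAtSensitivity:
    def test_enumerated_operating_points(self):
        s = make_sample([0.9, 0.8, 0.7, 0.1], [1, 1, 1, 1])
        s = make_sample(
            [0.9, 0.8, 0.7, 0.1, 0.5], [1, 1, 1, 1, 0]
        )
        thr = threshold_at_sensitivity(s, target=0.75)
        assert thr < 0.7 and np.isclose(thr, 0.7)
        # the threshold achieves the target under the score > threshold rule
        pos = s.y_true == 1
        assert (s.y_pred[pos] > thr).mean() >= 0.75

    def test_target_one_sits_below_minimum_positive(self):
        s = make_sample([0.9, 0.3, 0.5], [1, 1, 0])
        thr = threshold_at_sensitivity(s, target=1.0)
        assert thr < 0.3 and np.isclose(thr, 0.3)

    def test_target_zero_needs_no_alarms(self):
        s = make_sample([0.9, 0.3, 0.5], [1, 1, 0])
        assert threshold_at_sensitivity(s, target=0.0) == 0.9

    def test_unreachable_target_errors(self):
        s = make_sample([0.0, 0.5], [1, 0])
        with pytest.raises(UnreachableTargetError):
            threshold_at_sensitivity(s, target=1.0)


class TestAlarmRates:
    def _trajectory(self, scores, is_sepsis=False, onset_bin=None):
        return Trajectory(
            stay_id="t", scores=np.asarray(scores, dtype=float),
            is_sepsis=is_sepsis, onset_bin=onset_bin or len(scores),
        )

    def test_silencing_walk(self):
        # alarms at bins {1, 2, 3, 8}; a 4 h window keeps {1, 8}
        scores = np.array([0.1, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.9, 0.1])
        t = self._trajectory(scores, is_sepsis=True)
        summary = alarm_rates([t], threshold=0.5, silencing=4)
        assert summary.rate_sepsis == pytest.approx(4 / 10)
        assert summary.silenced_rate_sepsis == pytest.approx(2 / 10)

    def test_no_alarms_below_threshold(self):
        t = self._trajectory([0.1, 0.2, 0.3])
        s = alarm_rates([t], threshold=0.9)
        assert s.rate_control == 0.0 and s.silenced_rate_control == 0.0

    def test_zero_silencing_is_identity(self):
        t = self._trajectory([0.9, 0.9, 0.1, 0.9])
        s = alarm_rates([t], threshold=0.5, silencing=0)
        assert s.silenced_rate_control == s.rate_control

    def test_only_pre_onset_bins_counted(self):
        t = self._trajectory([0.9, 0.9, 0.9, 0.9], is_sepsis=True, onset_bin=2)
        s = alarm_rates([t], threshold=0.5, silencing=0)
        assert s.rate_sepsis == pytest.approx(1.0)  # 2 alarms / 2 patient-hours
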