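"""Weighted discrimination, calibration, and clinical-utility metrics.

All metrics consume an :class:`~sepsiseval.evaluation.EvaluationSample` and
respect its record weights, so they apply uniformly to per-stay samples (all
weights 1) and to inverse-frequency-weighted continuous samples.  The alarm rule
is strictly ``score > threshold`` everywhere (ROC/PR operating points, decision
curves, and alarm rates) so operating points stay mutually consistent.

Discrimination metrics are implemented directly in their weighted tied-rank
form:  AUROC is the weighted probability that a random positive outranks a
random negative (ties credited 1/2), and the PR curve is the weighted step-wise
curve with linear interpolation used only for precision-at-recall queries.
Prevalence-sensitive metrics come in "lifted" variants divided by the sample
prevalence, which equal ~1 for an uninformative model and so stay comparable
when the horizon shifts the fraction of positive bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import ConfigurationError, UndefinedMetricError, UnreachableTargetError
from .evaluation import EvaluationSample, Trajectory


@dataclass(frozen=True)
class MetricResult:
    name: str
    value: float
    threshold: float | None = None
    prevalence: float | None = None
    n_records: int = 0
    n_stays: int = 0
    flag: str | None = None


@dataclass(frozen=True)
class DecisionCurve:
    """Net benefit of score-thresholded alerting against the two trivial policies."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float


@dataclass(frozen=True)
class AlarmSummary:
    """Alarms per pre-onset patient-hour, before and after silencing."""

    threshold: float
    rate_sepsis: float
    rate_control: float
    silenced_rate_sepsis: float
    silenced_rate_control: float
    silencing: int


def _check_two_classes(sample: EvaluationSample, metric: str) -> None:
    y = sample.y_true
    if y.size == 0 or np.all(y == 1) or np.all(y == 0):
        raise UndefinedMetricError(
            f"{metric} undefined: sample"
            f"{'' if sample.config is None else ' ' + sample.config.strategy}"
            " contains a single class"
        )


def _auroc(y_true: np.ndarray, y_pred: np.ndarray, weights: np.ndarray) -> float:
    """Weighted P(score_pos > score_neg) + 0.5 P(tie); exact tied-rank form."""
    order = np.argsort(y_pred, kind="mergesort")
    s = y_pred[order]
    w_pos = np.where(y_true[order] == 1, weights[order], 0.0)
    w_neg = np.where(y_true[order] == 0, weights[order], 0.0)
    # tie-group boundaries over the sorted scores
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    g_pos = np.add.reduceat(w_pos, starts)
    g_neg = np.add.reduceat(w_neg, starts)
    cum_neg_before = np.concatenate(([0.0], np.cumsum(g_neg)[:-1]))
    num = float(np.sum(g_pos * (cum_neg_before + 0.5 * g_neg)))
    return num / (w_pos.sum() * w_neg.sum())


def weighted_auroc(sample: EvaluationSample) -> MetricResult:
    """Area under the weighted ROC curve (rank-sum formulation, ties = 1/2)."""
    _check_two_classes(sample, "AUROC")
    value = _auroc(sample.y_true, sample.y_pred, sample.weights)
    return MetricResult(
        "auroc", value, prevalence=sample.prevalence,
        n_records=sample.n_records, n_stays=sample.n_stays,
    )


def _pr_operating_points(sample: EvaluationSample):
    """Weighted PR operating points at thresholds just below each unique score.

    Returns (unique scores descending, precision, recall); point *i* is the
    confusion at any threshold t with ``s_{i+1} <= t < s_i`` under the
    ``score > t`` alarm rule, i.e. alarms fire for all records scoring >= s_i.
    """
    order = np.argsort(-sample.y_pred, kind="mergesort")
    s = sample.y_pred[order]
    w = sample.weights[order]
    tp_w = np.where(sample.y_true[order] == 1, w, 0.0)
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    uniq = s[starts]
    cum_tp = np.add.reduceat(tp_w, starts).cumsum()
    cum_all = np.add.reduceat(w, starts).cumsum()
    w_pos = tp_w.sum()
    precision = cum_tp / cum_all
    recall = cum_tp / w_pos
    return uniq, precision, recall


def _confusion_at(sample: EvaluationSample, threshold: float):
    alarm = sample.y_pred > threshold
    pos = sample.y_true == 1
    w = sample.weights
    tp = float(w[alarm & pos].sum())
    fp = float(w[alarm & ~pos].sum())
    fn = float(w[~alarm & pos].sum())
    tn = float(w[~alarm & ~pos].sum())
    return tp, fp, fn, tn


def auprc(sample: EvaluationSample) -> float:
    """Area under the weighted step-wise precision-recall curve."""
    _check_two_classes(sample, "AUPRC")
    _, precision, recall = _pr_operating_points(sample)
    dr = np.diff(np.concatenate(([0.0], recall)))
    return float(np.sum(dr * precision))


def precision_at_recall(sample: EvaluationSample, recall_target: float) -> float:
    """Precision at a target recall, linearly interpolated between operating points."""
    _check_two_classes(sample, "precision_at_recall")
    _, precision, recall = _pr_operating_points(sample)
    return float(np.interp(recall_target, recall, precision))


def pr_curve_metrics(
    sample: EvaluationSample,
    threshold: float = 0.5,
    recall_target: float | None = None,
) -> dict[str, MetricResult]:
    """AUPRC plus threshold metrics (PPV, NPV, recall) at the given threshold.

    When ``recall_target`` is given, the interpolated precision at that recall
    is reported as ``precision_at_recall``.
    """
    _check_two_classes(sample, "PR metrics")
    tp, fp, fn, tn = _confusion_at(sample, threshold)
    meta = dict(
        prevalence=sample.prevalence,
        n_records=sample.n_records,
        n_stays=sample.n_stays,
    )
    out = {
        "auprc": MetricResult("auprc", auprc(sample), **meta),
        "ppv": MetricResult(
            "ppv", tp / (tp + fp) if tp + fp > 0 else np.nan, threshold, **meta
        ),
        "npv": MetricResult(
            "npv", tn / (tn + fn) if tn + fn > 0 else np.nan, threshold, **meta
        ),
        "recall": MetricResult("recall", tp / (tp + fn), threshold, **meta),
    }
    if recall_target is not None:
        out["precision_at_recall"] = MetricResult(
            "precision_at_recall",
            precision_at_recall(sample, recall_target),
            **meta,
        )
    return out


def lifted_metrics(
    sample: EvaluationSample, threshold: float = 0.5
) -> dict[str, MetricResult]:
    """Prevalence-normalized metrics: PPV/prev, AUPRC/prev, recall at 2x-prev precision.

    ``recall_at_2prev`` scans the achievable operating points and takes the
    maximum recall among points with precision >= 2 * prevalence; if no point
    qualifies the value is 0 with a flag.
    """
    _check_two_classes(sample, "lifted metrics")
    prev = sample.prevalence
    if prev == 0:
        raise UndefinedMetricError("lifted metrics undefined at zero prevalence")
    base = pr_curve_metrics(sample, threshold=threshold)
    _, precision, recall = _pr_operating_points(sample)
    ok = precision >= 2.0 * prev
    if np.any(ok):
        r2p, flag = float(np.max(recall[ok])), None
    else:
        r2p, flag = 0.0, "precision_2prev_unreached"
    meta = dict(
        prevalence=prev, n_records=sample.n_records, n_stays=sample.n_stays
    )
    return {
        "lifted_ppv": MetricResult(
            "lifted_ppv", base["ppv"].value / prev, threshold, **meta
        ),
        "lifted_auprc": MetricResult(
            "lifted_auprc", base["auprc"].value / prev, **meta
        ),
        "recall_at_2prev": MetricResult(
            "recall_at_2prev", r2p, flag=flag, **meta
        ),
    }


def brier(sample: EvaluationSample) -> MetricResult:
    """Weighted mean squared difference between score and binary outcome."""
    s, y, w = sample.y_pred, sample.y_true, sample.weights
    if np.any((s < 0) | (s > 1)):
        raise ConfigurationError("Brier score requires scores in [0, 1]")
    value = float(np.sum(w * (s - y) ** 2) / np.sum(w))
    return MetricResult(
        "brier", value, prevalence=sample.prevalence,
        n_records=sample.n_records, n_stays=sample.n_stays,
    )


def calibrate_isotonic_cv(
    sample: EvaluationSample, folds: int = 5, seed: int = 0
) -> tuple[EvaluationSample, list[dict]]:
    """Cross-validated isotonic recalibration of the sample's scores.

    Stays are split into ``folds`` groups (seeded, stay-level so records of one
    stay never straddle the train/test boundary); per fold a monotone
    non-decreasing map is fitted on the weighted training records and applied to
    the held-out records.  The pooled calibrated sample is returned together
    with per-fold summaries.  Ranking — hence AUROC — is unchanged up to ties.
    """
    stays = np.asarray(list(dict.fromkeys(sample.stay_ids.tolist())), dtype=object)
    if stays.size < 2 * folds:
        raise UndefinedMetricError(
            f"isotonic calibration needs >= {2 * folds} stays, got {stays.size}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(stays.size)
    fold_of_stay = {stays[j]: i % folds for i, j in enumerate(perm)}
    fold_idx = np.asarray([fold_of_stay[s] for s in sample.stay_ids])

    calibrated = np.empty_like(sample.y_pred)
    summaries = []
    for k in range(folds):
        test = fold_idx == k
        train = ~test
        y_tr = sample.y_true[train]
        if np.all(y_tr == 1) or np.all(y_tr == 0):
            raise UndefinedMetricError(
                f"fold {k} is single-class; use a different seed or a larger sample"
            )
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(sample.y_pred[train], y_tr, sample_weight=sample.weights[train])
        calibrated[test] = iso.predict(sample.y_pred[test])
        summaries.append(
            {
                "fold": k,
                "n_train": int(train.sum()),
                "n_test": int(test.sum()),
                "knots": int(np.asarray(iso.X_thresholds_).size),
            }
        )
    return _dc_replace(sample, y_pred=calibrated), summaries


def decision_curve(
    sample: EvaluationSample, thresholds: Sequence[float] | None = None
) -> DecisionCurve:
    """Net benefit NB(p_t) = TP/N - (FP/N) * p_t / (1 - p_t) over a threshold grid.

    Alarms fire at ``score > p_t`` (calibrated scores expected); treat-all and
    treat-none reference policies are included.  Default grid 0.01..0.50 step
    0.01.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.501, 0.01), 4)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ConfigurationError("decision-curve thresholds must lie in (0, 1)")
    n_total = float(np.sum(sample.weights))
    prev = sample.prevalence
    odds = thresholds / (1.0 - thresholds)
    nb = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        tp, fp, _, _ = _confusion_at(sample, pt)
        nb[i] = tp / n_total - (fp / n_total) * odds[i]
    return DecisionCurve(
        thresholds=thresholds,
        net_benefit=nb,
        treat_all=prev - (1.0 - prev) * odds,
        treat_none=np.zeros_like(thresholds),
        prevalence=prev,
    )


def threshold_at_sensitivity(sample: EvaluationSample, target: float = 0.80) -> float:
    """Largest threshold whose weighted recall reaches the target sensitivity.

    With the ``score > threshold`` alarm rule the returned value is the largest
    qualifying positive score nudged just below itself (so that score fires),
    matching the convention that recall is evaluated at thresholds immediately
    below achievable scores.  ``target == 0`` returns the maximum score (no
    alarms needed).  Raises :class:`UnreachableTargetError` when no
    non-negative threshold reaches the target.
    """
    if not (0 <= target <= 1):
        raise ConfigurationError("target sensitivity must lie in [0, 1]")
    pos = sample.y_true == 1
    if not np.any(pos):
        raise UndefinedMetricError("no positives; sensitivity threshold undefined")
    if target == 0:
        return float(np.max(sample.y_pred))
    s_pos = sample.y_pred[pos]
    w_pos = sample.weights[pos]
    order = np.argsort(-s_pos, kind="mergesort")
    s_sorted = s_pos[order]
    recall = np.cumsum(w_pos[order]) / w_pos.sum()
    ok = recall >= target - 1e-12
    candidates = s_sorted[ok]
    best = float(np.max(candidates))  # largest score still achieving the target
    thr = float(np.nextafter(best, -np.inf))
    if thr < 0:
        raise UnreachableTargetError(
            f"sensitivity {target} unreachable with a non-negative threshold"
        )
    return thr


def _silence(alarm_bins: np.ndarray, silencing: int) -> np.ndarray:
    """Keep alarms not suppressed by a preceding unsilenced alarm.

    An unsilenced alarm at bin t suppresses bins t+1 .. t+silencing; suppressed
    alarms do not extend the suppression.
    """
    kept = []
    next_allowed = -1
    for b in alarm_bins:
        if b >= next_allowed:
            kept.append(b)
            next_allowed = b + silencing + 1
    return np.asarray(kept, dtype=int)


def alarm_rates(
    trajectories: Sequence[Trajectory], threshold: float, silencing: int = 4
) -> AlarmSummary:
    """Alarms per patient-hour for septic vs control stays, with silencing.

    Bins are restricted to the pre-onset range [0, onset_bin); the denominator
    is the number of pre-onset patient-hours per group.  Controls without an
    assigned onset use all observed bins.
    """
    counts = {True: [0, 0, 0], False: [0, 0, 0]}  # raw, silenced, hours
    for t in trajectories:
        stop = t.onset_bin if t.onset_bin is not None else t.last_bin + 1
        scores = t.scores[:stop]
        alarm_bins = np.flatnonzero(scores > threshold)
        c = counts[t.is_sepsis]
        c[0] += alarm_bins.size
        c[1] += _silence(alarm_bins, silencing).size if silencing > 0 else alarm_bins.size
        c[2] += stop
    def _rate(n, hours):
        return n / hours if hours > 0 else 0.0
    return AlarmSummary(
        threshold=threshold,
        rate_sepsis=_rate(counts[True][0], counts[True][2]),
        rate_control=_rate(counts[False][0], counts[False][2]),
        silenced_rate_sepsis=_rate(counts[True][1], counts[True][2]),
        silenced_rate_control=_rate(counts[False][1], counts[False][2]),
        silencing=silencing,
    )
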