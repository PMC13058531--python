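"""Sepsis-3 onset labeling from antibiotic exposure and SOFA trajectories.

Sepsis-3 defines sepsis as a suspected infection accompanied by an acute increase of
the SOFA organ-dysfunction score by at least 2 points.  In EHR cohorts without
microbiology records, suspicion of infection (SI) is commonly inferred from a
sustained antibiotic course: at least one dose every 24 hours spanning at least
3 days, with the SI time set to the first dose of the course.  A qualifying SOFA
rise must then occur inside the SI window, from 48 hours before to 24 hours after
the SI time; the onset time is the time of the recorded SOFA increase.

The SOFA reference ("baseline") against which the rise is measured is not uniquely
pinned down by the consensus definition.  The default here is the running minimum of
the SOFA values observed earlier within the same window, the least restrictive
common operationalization; ``baseline="window_first"`` compares against the first
value in the window instead.

This module also implements the cohort eligibility filters: ICU origin, adult age,
onset at least 4 hours after admission, at least 6 hours of data, no measurement gap
of 12 hours or more, and truncation of every stay at 7 days (onsets beyond the
truncation demote the stay to a control).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractViolationError

#: SI window extent relative to the SI time, in hours.
SI_WINDOW_BEFORE = 48.0
SI_WINDOW_AFTER = 24.0

#: Exclusion reason categories, in reporting order.
EXCLUSION_REASONS = (
    "non_icu_origin",
    "age_lt_18",
    "onset_lt_4h",
    "data_lt_6h",
    "gap_ge_12h",
)


@dataclass(frozen=True)
class AntibioticCourse:
    """A maximal run of antibiotic doses with gaps <= 24 h spanning >= 72 h."""

    start: float
    end: float
    dose_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.dose_times and self.start != self.dose_times[0]:
            raise ContractViolationError("course start must equal the first dose time")


@dataclass(frozen=True)
class SuspicionWindow:
    """SI window [t_si - 48 h, t_si + 24 h]; the start is clipped at admission."""

    t_si: float
    window_start: float
    window_end: float

    @classmethod
    def from_si_time(
        cls,
        t_si: float,
        before: float = SI_WINDOW_BEFORE,
        after: float = SI_WINDOW_AFTER,
    ) -> "SuspicionWindow":
        return cls(t_si=t_si, window_start=t_si - before, window_end=t_si + after)

    @property
    def clipped_start(self) -> float:
        return max(self.window_start, 0.0)


@dataclass
class SepsisLabel:
    """Per-stay sepsis status with the onset time and its provenance."""

    stay_id: str
    is_sepsis: bool
    t_onset: float | None = None
    si_time: float | None = None
    sofa_delta: int | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.is_sepsis and self.t_onset is None:
            raise ContractViolationError("a sepsis label requires an onset time")


@dataclass
class EligibilityReport:
    """Outcome of the cohort filters for one stay; included iff no reasons."""

    stay_id: str
    exclusion_reasons: list[str] = field(default_factory=list)
    truncated_at: float | None = None

    @property
    def included(self) -> bool:
        return not self.exclusion_reasons


def find_antibiotic_courses(
    dose_times: Sequence[float],
    min_span: float = 72.0,
    max_gap: float = 24.0,
) -> list[AntibioticCourse]:
    """Identify sustained antibiotic courses in a sorted sequence of dose times.

    A course is a maximal run of doses in which consecutive doses are at most
    ``max_gap`` hours apart and the span from first to last dose is at least
    ``min_span`` hours.  The SI time associated with a course is its first dose.

    Raises :class:`ContractViolationError` if ``dose_times`` is unsorted or
    contains negative times.
    """
    times = np.asarray(dose_times, dtype=float)
    if times.size == 0:
        return []
    if np.any(np.diff(times) < 0):
        raise ContractViolationError("dose_times must be sorted ascending")
    if times[0] < 0:
        raise ContractViolationError("dose_times must be non-negative")

    courses: list[AntibioticCourse] = []
    run_breaks = np.flatnonzero(np.diff(times) > max_gap) + 1
    for run in np.split(times, run_breaks):
        if run[-1] - run[0] >= min_span:
            courses.append(
                AntibioticCourse(
                    start=float(run[0]), end=float(run[-1]), dose_times=tuple(run)
                )
            )
    return courses


def suspicion_windows(
    courses: Iterable[AntibioticCourse],
    before: float = SI_WINDOW_BEFORE,
    after: float = SI_WINDOW_AFTER,
) -> list[SuspicionWindow]:
    """One SI window per antibiotic course, anchored at the course start."""
    return [SuspicionWindow.from_si_time(c.start, before, after) for c in courses]


def detect_onset(
    stay_id: str,
    windows: Sequence[SuspicionWindow],
    sofa: Sequence[tuple[float, int]],
    delta_min: int = 2,
    baseline: str = "running_min",
) -> SepsisLabel:
    """Scan the SI windows for a qualifying SOFA rise and return the sepsis label.

    Within each window (using the admission-clipped interval), SOFA points are
    scanned in time order; an onset fires at the first time ``t`` where
    ``score(t) - reference >= delta_min``.  With ``baseline="running_min"`` the
    reference is the minimum of strictly earlier points within the window; with
    ``baseline="window_first"`` it is the first point in the window.  The earliest
    firing time across all windows is the onset.

    An empty SOFA series with non-empty windows yields a non-sepsis label carrying
    a ``warning`` flag rather than an error.
    """
    if baseline not in ("running_min", "window_first"):
        raise ContractViolationError(f"unknown SOFA baseline rule: {baseline!r}")
    sofa_t = np.asarray([t for t, _ in sofa], dtype=float)
    sofa_s = np.asarray([s for _, s in sofa], dtype=float)
    if np.any(np.diff(sofa_t) < 0):
        raise ContractViolationError("SOFA series must be sorted by time")
    if sofa_t.size == 0:
        warning = "no_sofa_data" if windows else None
        return SepsisLabel(stay_id=stay_id, is_sepsis=False, warning=warning)

    best: tuple[float, float, int] | None = None  # (t_onset, t_si, delta)
    for w in sorted(windows, key=lambda w: w.t_si):
        lo, hi = w.clipped_start, w.window_end
        in_w = (sofa_t >= lo) & (sofa_t <= hi)
        if not np.any(in_w):
            continue
        t_w, s_w = sofa_t[in_w], sofa_s[in_w]
        for i in range(1, len(t_w)):
            if baseline == "running_min":
                ref = float(np.min(s_w[:i]))
            else:
                ref = float(s_w[0])
            delta = s_w[i] - ref
            if delta >= delta_min:
                cand = (float(t_w[i]), w.t_si, int(delta))
                if best is None or cand[0] < best[0]:
                    best = cand
                break
    if best is None:
        return SepsisLabel(stay_id=stay_id, is_sepsis=False)
    t_onset, t_si, delta = best
    return SepsisLabel(
        stay_id=stay_id, is_sepsis=True, t_onset=t_onset, si_time=t_si, sofa_delta=delta
    )


def label_stay(
    stay,
    min_span: float = 72.0,
    max_gap: float = 24.0,
    delta_min: int = 2,
    baseline: str = "running_min",
) -> SepsisLabel:
    """Label one :class:`~sepsiseval.synthetic_cohort.RawStay` end to end."""
    dose_times = sorted(t for _, t in stay.abx_events)
    courses = find_antibiotic_courses(dose_times, min_span=min_span, max_gap=max_gap)
    windows = suspicion_windows(courses)
    return detect_onset(
        stay.stay_id, windows, stay.sofa_series, delta_min=delta_min, baseline=baseline
    )


def label_cohort(stays, **kwargs) -> list[SepsisLabel]:
    return [label_stay(s, **kwargs) for s in stays]


def apply_eligibility(
    stays,
    labels: Sequence[SepsisLabel],
    max_stay: float = 168.0,
    min_data_span: float = 6.0,
    max_data_gap: float = 12.0,
    min_onset: float = 4.0,
) -> tuple[list[str], list[EligibilityReport], list[SepsisLabel]]:
    """Apply the cohort filters; returns (included ids, reports, updated labels).

    Filters: non-ICU admission origin, age < 18 years, sepsis onset strictly
    before ``min_onset`` hours, total measurement span (union over all
    time-varying features, within the truncation window) below ``min_data_span``
    hours, and any inter-measurement gap of ``max_data_gap`` hours or more.
    Retained stays are truncated at ``max_stay`` hours; a case whose onset lies
    beyond the truncation is relabeled as a control (the label update is the
    reason labels are returned).
    """
    by_id = {l.stay_id: l for l in labels}
    missing = [s.stay_id for s in stays if s.stay_id not in by_id]
    if missing:
        raise ContractViolationError(f"labels missing for stays: {missing[:5]}")

    included: list[str] = []
    reports: list[EligibilityReport] = []
    updated: list[SepsisLabel] = []
    for stay in stays:
        label = by_id[stay.stay_id]
        reasons: list[str] = []
        if getattr(stay, "admission_origin", "icu") != "icu":
            reasons.append("non_icu_origin")
        if stay.age < 18:
            reasons.append("age_lt_18")

        times = np.sort(
            np.asarray([t for _, t, _ in stay.measurements], dtype=float)
        )
        truncated_at = None
        if times.size and times[-1] > max_stay:
            truncated_at = max_stay
        times = times[times <= max_stay]
        span = float(times[-1] - times[0]) if times.size else 0.0
        if span < min_data_span:
            reasons.append("data_lt_6h")
        if times.size >= 2 and float(np.max(np.diff(times))) >= max_data_gap:
            reasons.append("gap_ge_12h")

        if label.is_sepsis and label.t_onset is not None and label.t_onset > max_stay:
            # onset beyond the truncation window: stay becomes a control
            label = replace(
                label, is_sepsis=False, t_onset=None, sofa_delta=None,
                warning="onset_beyond_truncation",
            )
        if label.is_sepsis and label.t_onset is not None and label.t_onset < min_onset:
            reasons.append("onset_lt_4h")

        report = EligibilityReport(
            stay_id=stay.stay_id, exclusion_reasons=reasons, truncated_at=truncated_at
        )
        reports.append(report)
        updated.append(label)
        if report.included:
            included.append(stay.stay_id)
    return included, reports, updated
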