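"""Sepsis-3 labeling: antibiotic courses, SI windows, onset detection, filters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sepsiseval import (
    CohortConfig,
    ContractViolationError,
    SepsisLabel,
    SuspicionWindow,
    apply_eligibility,
    detect_onset,
    find_antibiotic_courses,
    generate_ehr_cohort,
    label_cohort,
    suspicion_windows,
)
from sepsiseval.synthetic_cohort import RawStay


def _windows(*si_times):
    return [SuspicionWindow.from_si_time(t) for t in si_times]


class TestAntibioticCourses:
    @pytest.mark.parametrize(
        "doses, expected_si",
        [
            ([0, 20, 40, 60, 72], [0.0]),          # gaps <= 24, span 72
            ([0, 30], []),                          # gap 30 > 24 breaks the run
            ([0, 24, 48, 71], []),                  # span 71 < 72
            ([0, 24, 48, 72, 100, 130], [0.0]),     # gap 28 then 30 split the tail off
            ([], []),
            ([10, 30, 50, 70, 82], [10.0]),
        ],
    )
    def test_course_detection(self, doses, expected_si):
        courses = find_antibiotic_courses(doses)
        assert [c.start for c in courses] == expected_si

    def test_course_detection_matches_enumeration(self, rng):
        """Greedy run-splitting agrees with brute-force enumeration of runs."""

        def oracle(times, min_span=72.0, max_gap=24.0):
            runs, cur = [], []
            for t in times:
                if cur and t - cur[-1] > max_gap:
                    runs.append(cur)
                    cur = []
                cur.append(t)
            if cur:
                runs.append(cur)
            return [r[0] for r in runs if r[-1] - r[0] >= min_span]

        for _ in range(200):
            k = rng.integers(0, 12)
            times = np.sort(rng.uniform(0, 200, k)).round(1).tolist()
            got = [c.start for c in find_antibiotic_courses(times)]
            assert got == oracle(times)

    def test_unsorted_doses_rejected(self):
        with pytest.raises(ContractViolationError):
            find_antibiotic_courses([10, 5, 60])

    @given(
        doses=st.lists(
            st.floats(0, 150, allow_nan=False), min_size=2, max_size=10
        ),
        extra=st.floats(0, 150, allow_nan=False),
    )
    def test_adding_a_dose_never_removes_a_course(self, doses, extra):
        """Monotonicity: an extra dose can only create/extend courses and
        never delays the earliest SI time."""
        base = sorted(doses)
        before = find_antibiotic_courses(base)
        after = find_antibiotic_courses(sorted(base + [extra]))
        if before:
            assert after
            assert after[0].start <= before[0].start

    def test_si_window_arithmetic(self):
        for t_si in (0.0, 10.0, 100.0):
            doses = [t_si + d for d in (0, 20, 40, 60, 72)]
            (w,) = suspicion_windows(find_antibiotic_courses(doses))
            assert w.window_end - w.window_start == 72.0
            assert w.window_start == t_si - 48.0
            assert w.clipped_start == max(0.0, t_si - 48.0)


class TestOnsetDetection:
    def test_qualifying_rise_inside_window(self):
        label = detect_onset("x", _windows(60.0), [(40.0, 2), (70.0, 5)])
        assert label.is_sepsis and label.t_onset == 70.0 and label.sofa_delta == 3

    def test_rise_of_one_is_not_sepsis(self):
        label = detect_onset("x", _windows(60.0), [(40.0, 2), (70.0, 3), (80.0, 3)])
        assert not label.is_sepsis

    def test_earliest_onset_across_windows(self):
        sofa = [(20.0, 2), (30.0, 4), (80.0, 2), (90.0, 5)]
        label = detect_onset("x", _windows(25.0, 95.0), sofa)
        assert label.t_onset == 30.0

    def test_empty_sofa_gives_flagged_control(self):
        label = detect_onset("x", _windows(10.0), [])
        assert not label.is_sepsis and label.warning == "no_sofa_data"

    def test_running_min_baseline(self):
        # dip to 1 then rise to 3: qualifies against the running minimum
        label = detect_onset("x", _windows(50.0), [(10.0, 4), (20.0, 1), (40.0, 3)])
        assert label.is_sepsis and label.t_onset == 40.0 and label.sofa_delta == 2

    def test_matches_bruteforce_pair_scan(self, rng):
        """On random stays the scan equals a brute force over all
        (window, earlier-point, point) combinations."""

        def oracle(windows, sofa, delta=2):
            hits = []
            for w in windows:
                lo, hi = max(w.window_start, 0.0), w.window_end
                pts = [(t, s) for t, s in sofa if lo <= t <= hi]
                for i, (t, s) in enumerate(pts):
                    if any(s - s_u >= delta for _, s_u in pts[:i]):
                        hits.append(t)
                        break
            return min(hits) if hits else None

        for _ in range(50):
            n_w = int(rng.integers(1, 4))
            windows = _windows(*rng.uniform(0, 120, n_w))
            n_p = int(rng.integers(0, 15))
            sofa = sorted(
                zip(rng.uniform(0, 150, n_p), rng.integers(0, 8, n_p))
            )
            sofa = [(float(t), int(s)) for t, s in sofa]
            label = detect_onset("x", windows, sofa)
            assert label.t_onset == oracle(windows, sofa)


def _stay(stay_id="s", age=50.0, measurements=None, origin="icu"):
    if measurements is None:
        measurements = [("heart_rate", float(t), 80.0) for t in range(0, 30)]
    return RawStay(
        stay_id=stay_id, age=age, sex="m", height=175, weight=80,
        measurements=measurements, abx_events=[], sofa_series=[(2.0, 1)],
        admission_origin=origin,
    )


class TestEligibility:
    def _run(self, stay, label=None):
        label = label or SepsisLabel(stay.stay_id, False)
        return apply_eligibility([stay], [label])

    def test_short_stay_excluded(self):
        m = [("heart_rate", t, 80.0) for t in np.arange(0, 5, 0.5)]
        _, (rep,), _ = self._run(_stay(measurements=m))
        assert rep.exclusion_reasons == ["data_lt_6h"]

    def test_early_onset_excluded(self):
        _, (rep,), _ = self._run(
            _stay(), SepsisLabel("s", True, t_onset=3.5)
        )
        assert "onset_lt_4h" in rep.exclusion_reasons

    def test_onset_at_exactly_4h_included(self):
        _, (rep,), _ = self._run(_stay(), SepsisLabel("s", True, t_onset=4.0))
        assert rep.included

    def test_long_gap_excluded(self):
        m = [("heart_rate", float(t), 80.0) for t in list(range(21)) + list(range(40, 61))]
        _, (rep,), _ = self._run(_stay(measurements=m))
        assert rep.exclusion_reasons == ["gap_ge_12h"]

    def test_non_icu_and_minor_excluded(self):
        _, (rep,), _ = self._run(_stay(age=17, origin="ward"))
        assert rep.exclusion_reasons == ["non_icu_origin", "age_lt_18"]

    def test_late_onset_demotes_case_to_control(self):
        m = [("heart_rate", float(t), 80.0) for t in range(0, 180, 1)]
        _, (rep,), (label,) = self._run(
            _stay(measurements=m), SepsisLabel("s", True, t_onset=170.0)
        )
        assert rep.included and rep.truncated_at == 168.0
        assert not label.is_sepsis and label.warning == "onset_beyond_truncation"


class TestGeneratorLabelerConsistency:
    def test_planted_case_recovered_exactly(self):
        stay = _stay()
        stay.abx_events = [("a", t) for t in [50.0, 70.0, 90.0, 110.0, 130.0]]
        stay.sofa_series = [(10.0, 2), (30.0, 2), (60.0, 5), (100.0, 5)]
        (label,) = label_cohort([stay])
        assert label.is_sepsis and label.t_onset == 60.0 and label.si_time == 50.0

    def test_two_isolated_doses_not_si(self):
        stay = _stay()
        stay.abx_events = [("a", 50.0), ("a", 90.0)]
        stay.sofa_series = [(10.0, 1), (60.0, 5)]
        (label,) = label_cohort([stay])
        assert not label.is_sepsis

    def test_labeler_recovers_planted_assignment(self):
        """Sensitivity and specificity >= 0.95 on a 500-stay raw cohort."""
        raw = generate_ehr_cohort(CohortConfig(n_stays=500, seed=7))
        pred = {l.stay_id: l.is_sepsis for l in label_cohort(raw.stays)}
        truth = dict(zip(raw.truth["stay_id"], raw.truth["is_sepsis"]))
        tp = sum(pred[s] and truth[s] for s in pred)
        fn = sum(not pred[s] and truth[s] for s in pred)
        fp = sum(pred[s] and not truth[s] for s in pred)
        tn = sum(not pred[s] and not truth[s] for s in pred)
        assert tp / (tp + fn) >= 0.95
        assert tn / (tn + fp) >= 0.95
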