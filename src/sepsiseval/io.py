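"""CSV dialects for cohorts, labels, samples and reports.

All on-disk formats are plain delimited text:

* raw stays — long format ``(stay_id, kind, name, time_h, value)`` with
  ``kind`` in {measurement, abx, sofa, static};
* score cohorts — ``scores.csv (stay_id, bin, score)`` plus a stay-level
  ``stays.csv (stay_id, is_sepsis, onset_h, last_bin)``;
* labels — ``(stay_id, is_sepsis, onset_h, si_h, sofa_delta)``;
* evaluation samples — ``(stay_id, bin, y_pred, y_true, weight)``;
* plausibility ranges — ``(feature, lower, upper)``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractViolationError
from .evaluation import EvaluationSample, Trajectory
from .labeling import EligibilityReport, SepsisLabel
from .synthetic_cohort import RawStay, ScoreCohort

_STATIC_ORDER = ("age", "sex", "height", "weight", "admission_origin")
_SEX_CODE = {"m": 0.0, "f": 1.0}
_SEX_DECODE = {0.0: "m", 1.0: "f"}
_ORIGIN_CODE = {"icu": 0.0, "ward": 1.0}
_ORIGIN_DECODE = {0.0: "icu", 1.0: "ward"}


def write_raw_stays(stays: Sequence[RawStay], path: str | Path) -> None:
    rows = []
    for s in stays:
        rows.append((s.stay_id, "static", "age", 0.0, s.age))
        rows.append((s.stay_id, "static", "sex", 0.0, _SEX_CODE[s.sex]))
        rows.append((s.stay_id, "static", "height", 0.0, s.height))
        rows.append((s.stay_id, "static", "weight", 0.0, s.weight))
        rows.append(
            (s.stay_id, "static", "admission_origin", 0.0,
             _ORIGIN_CODE[s.admission_origin])
        )
        rows.extend((s.stay_id, "measurement", n, t, v) for n, t, v in s.measurements)
        rows.extend((s.stay_id, "abx", d, t, 1.0) for d, t in s.abx_events)
        rows.extend((s.stay_id, "sofa", "sofa", t, float(v)) for t, v in s.sofa_series)
    pd.DataFrame(
        rows, columns=["stay_id", "kind", "name", "time_h", "value"]
    ).to_csv(path, index=False)


def read_raw_stays(path: str | Path) -> list[RawStay]:
    df = pd.read_csv(path)
    required = {"stay_id", "kind", "name", "time_h", "value"}
    if not required.issubset(df.columns):
        raise ContractViolationError(
            f"raw stay CSV must have columns {sorted(required)}"
        )
    stays = []
    for sid, g in df.groupby("stay_id", sort=False):
        statics = {
            r.name: r.value for r in g[g["kind"] == "static"].itertuples()
        }
        meas = g[g["kind"] == "measurement"].sort_values("time_h")
        abx = g[g["kind"] == "abx"].sort_values("time_h")
        sofa = g[g["kind"] == "sofa"].sort_values("time_h")
        stays.append(
            RawStay(
                stay_id=str(sid),
                age=float(statics.get("age", np.nan)),
                sex=_SEX_DECODE.get(statics.get("sex"), "m"),
                height=float(statics.get("height", np.nan)),
                weight=float(statics.get("weight", np.nan)),
                measurements=[
                    (r.name, float(r.time_h), float(r.value))
                    for r in meas.itertuples()
                ],
                abx_events=[(r.name, float(r.time_h)) for r in abx.itertuples()],
                sofa_series=[
                    (float(r.time_h), int(r.value)) for r in sofa.itertuples()
                ],
                admission_origin=_ORIGIN_DECODE.get(
                    statics.get("admission_origin", 0.0), "icu"
                ),
            )
        )
    return stays


def write_score_cohort(
    cohort: ScoreCohort, scores_path: str | Path, stays_path: str | Path
) -> None:
    score_rows = []
    stay_rows = []
    for t, l in zip(cohort.trajectories, cohort.labels):
        score_rows.extend(
            (t.stay_id, b, s) for b, s in enumerate(t.scores)
        )
        stay_rows.append(
            (
                t.stay_id,
                int(t.is_sepsis),
                "" if l.t_onset is None else l.t_onset,
                t.last_bin,
            )
        )
    pd.DataFrame(score_rows, columns=["stay_id", "bin", "score"]).to_csv(
        scores_path, index=False
    )
    pd.DataFrame(
        stay_rows, columns=["stay_id", "is_sepsis", "onset_h", "last_bin"]
    ).to_csv(stays_path, index=False)


def read_trajectories(
    scores_path: str | Path, stays_path: str | Path
) -> list[Trajectory]:
    scores = pd.read_csv(scores_path)
    stays = pd.read_csv(stays_path)
    ids_scores = set(scores["stay_id"].astype(str))
    ids_stays = set(stays["stay_id"].astype(str))
    if ids_scores != ids_stays:
        raise ContractViolationError(
            "stay ids differ between scores and stays files; "
            f"e.g. {sorted(ids_scores ^ ids_stays)[:3]}"
        )
    by_stay = {
        str(sid): g.sort_values("bin")["score"].to_numpy()
        for sid, g in scores.groupby("stay_id", sort=False)
    }
    out = []
    for r in stays.itertuples():
        sid = str(r.stay_id)
        is_sepsis = bool(int(r.is_sepsis))
        onset_bin = None
        if is_sepsis and not pd.isna(r.onset_h):
            onset_bin = int(np.floor(float(r.onset_h)))
        out.append(
            Trajectory(
                stay_id=sid,
                scores=by_stay[sid],
                is_sepsis=is_sepsis,
                onset_bin=onset_bin,
            )
        )
    return out


def write_labels(labels: Sequence[SepsisLabel], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                l.stay_id,
                int(l.is_sepsis),
                "" if l.t_onset is None else l.t_onset,
                "" if l.si_time is None else l.si_time,
                "" if l.sofa_delta is None else l.sofa_delta,
            )
            for l in labels
        ],
        columns=["stay_id", "is_sepsis", "onset_h", "si_h", "sofa_delta"],
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> list[SepsisLabel]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        out.append(
            SepsisLabel(
                stay_id=str(r.stay_id),
                is_sepsis=bool(int(r.is_sepsis)),
                t_onset=None if pd.isna(r.onset_h) else float(r.onset_h),
                si_time=None if pd.isna(r.si_h) else float(r.si_h),
                sofa_delta=None if pd.isna(r.sofa_delta) else int(r.sofa_delta),
            )
        )
    return out


def write_exclusions(reports: Sequence[EligibilityReport], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                r.stay_id,
                int(r.included),
                ";".join(r.exclusion_reasons),
                "" if r.truncated_at is None else r.truncated_at,
            )
            for r in reports
        ],
        columns=["stay_id", "included", "reasons", "truncated_at"],
    ).to_csv(path, index=False)


def write_sample(sample: EvaluationSample, path: str | Path) -> None:
    sample.to_frame().to_csv(path, index=False)


def read_sample(path: str | Path) -> EvaluationSample:
    df = pd.read_csv(path)
    return EvaluationSample(
        stay_ids=df["stay_id"].astype(str).to_numpy(dtype=object),
        bins=df["bin"].to_numpy(dtype=float),
        y_pred=df["y_pred"].to_numpy(dtype=float),
        y_true=df["y_true"].to_numpy(dtype=int),
        weights=df["weight"].to_numpy(dtype=float),
    )


def write_ranges(ranges: pd.DataFrame, path: str | Path) -> None:
    ranges[["feature", "lower", "upper"]].to_csv(path, index=False)


def read_ranges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"feature", "lower", "upper"}
    if not required.issubset(df.columns):
        raise ContractViolationError(
            f"plausibility range CSV must have columns {sorted(required)}"
        )
    return df
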