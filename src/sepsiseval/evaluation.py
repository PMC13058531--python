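"""Strategy-specific evaluation-sample construction for sepsis prediction scores.

A model produces an hourly risk-score trajectory per ICU stay.  How those
trajectories are turned into (score, label) pairs — the *evaluation strategy* —
changes the apparent performance of the very same model on the very same data:

* **fixed horizon** — one score per stay, taken exactly ``h`` hours before the
  (actual or hypothetical) onset; stays shorter than the horizon are excluded.
* **peak score** — one score per stay, the maximum over all pre-onset bins
  (optionally restricted to the last ``h`` hours before onset).
* **continuous** — every pre-onset hourly score is a record; for cases, bins
  within ``h`` hours of onset are labeled positive, all other bins negative.
  Records are weighted 1/n_i per stay so that every stay contributes equally.

Controls have no onset, so an onset policy is required: without matching the
control "onset" is the end of the observed data (discharge or the 7-day
truncation); with *onset matching* each control copies the onset of a randomly
paired case whose onset does not exceed the control's stay, aligning the
length-of-stay distributions of the two groups.  Optionally controls are
down-sampled first to harmonize the patient-level prevalence across strategies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractViolationError

STRATEGIES = ("fixed_horizon", "peak_score", "continuous")


def derive_seed(seed: int, label: str) -> int:
    """Derive a component seed (< 2**31) deterministically from a master seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class Trajectory:
    """One stay's hourly risk scores with its onset bin.

    ``scores[t]`` is the model output for hourly bin ``t`` (bin ``t`` covers
    [t, t+1) hours since admission).  Cases carry ``onset_bin = floor(t_onset)``
    and their scores end at the onset bin; controls are generated with
    ``onset_bin=None`` until an onset policy assigns one.  The prediction at the
    onset bin itself is never evaluated by any strategy.
    """

    stay_id: str
    scores: np.ndarray
    is_sepsis: bool
    onset_bin: int | None = None
    matched_fallback: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ContractViolationError("a trajectory needs >= 1 hourly score bin")
        if not np.all(np.isfinite(self.scores)):
            raise ContractViolationError(f"non-finite scores in stay {self.stay_id}")
        if self.onset_bin is not None and not (
            0 < self.onset_bin <= self.last_bin + 1
        ):
            raise ContractViolationError(
                f"onset_bin {self.onset_bin} outside (0, last_bin+1] "
                f"for stay {self.stay_id}"
            )

    @property
    def last_bin(self) -> int:
        return self.scores.size - 1


@dataclass(frozen=True)
class StrategyConfig:
    """Full specification of one evaluation arm."""

    strategy: str
    h: int | None = None
    onset_matching: bool = False
    target_prevalence: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )
        if self.strategy != "peak_score" and (self.h is None or self.h < 1):
            raise ConfigurationError(f"h must be >= 1 for {self.strategy}")
        if self.h is not None and self.h < 1:
            raise ConfigurationError("h must be >= 1 when given")
        if self.target_prevalence is not None and not (
            0 < self.target_prevalence < 1
        ):
            raise ConfigurationError("target_prevalence must lie in (0, 1)")
        if (self.onset_matching or self.target_prevalence is not None) and (
            self.seed is None
        ):
            raise ConfigurationError(
                "seed is required when onset matching or harmonization is active"
            )


@dataclass
class EvaluationSample:
    """Flat (stay, bin, score, label, weight) records — the input of all metrics.

    Records are stored grouped by stay in trajectory order, which the bootstrap
    machinery relies on.  ``bins`` is NaN for per-stay (fixed-horizon source bin
    is kept for provenance; peak-score records have no single source bin).
    """

    stay_ids: np.ndarray
    bins: np.ndarray
    y_pred: np.ndarray
    y_true: np.ndarray
    weights: np.ndarray
    config: StrategyConfig | None = None
    n_excluded: int = 0
    excluded_ids: tuple = ()

    @property
    def n_records(self) -> int:
        return int(self.y_pred.size)

    @property
    def n_stays(self) -> int:
        return int(pd.unique(self.stay_ids).size)

    @property
    def prevalence(self) -> float:
        """Weighted positive fraction of the sample."""
        w = self.weights
        return float(np.sum(w[self.y_true == 1]) / np.sum(w))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stay_id": self.stay_ids,
                "bin": self.bins,
                "y_pred": self.y_pred,
                "y_true": self.y_true,
                "weight": self.weights,
            }
        )


def _as_record_sample(records, config, n_excluded=0, excluded_ids=()) -> EvaluationSample:
    if records:
        sid, bins, yp, yt, w = map(np.asarray, zip(*records))
    else:
        sid = np.asarray([], dtype=object)
        bins = yp = w = np.asarray([], dtype=float)
        yt = np.asarray([], dtype=int)
    return EvaluationSample(
        stay_ids=sid,
        bins=np.asarray(bins, dtype=float),
        y_pred=np.asarray(yp, dtype=float),
        y_true=np.asarray(yt, dtype=int),
        weights=np.asarray(w, dtype=float),
        config=config,
        n_excluded=n_excluded,
        excluded_ids=tuple(excluded_ids),
    )


def assign_control_onsets(
    trajectories: Sequence[Trajectory], matching: bool, seed: int | None = None
) -> list[Trajectory]:
    """Assign hypothetical onset bins to control trajectories.

    Without matching, the control onset is the end of the observed data
    (``last_bin + 1``, so every observed bin is usable).  With matching, each
    control copies the onset of a case drawn uniformly (with replacement) among
    cases whose ``onset_bin`` does not exceed the control's ``last_bin + 1``;
    controls with no eligible case fall back to the data end and are flagged.
    Case trajectories pass through unchanged.
    """
    cases = [t for t in trajectories if t.is_sepsis]
    if matching and not cases:
        raise ConfigurationError("onset matching requested but the cohort has no cases")
    if matching and seed is None:
        raise ConfigurationError("onset matching requires a seed")
    rng = np.random.default_rng(seed)
    case_onsets = np.asarray([t.onset_bin for t in cases], dtype=int)
    order = np.argsort(case_onsets, kind="mergesort")
    sorted_onsets = case_onsets[order]

    out: list[Trajectory] = []
    for t in trajectories:
        if t.is_sepsis:
            out.append(t)
            continue
        end = t.last_bin + 1
        if not matching:
            out.append(replace(t, onset_bin=end, matched_fallback=False))
            continue
        n_eligible = int(np.searchsorted(sorted_onsets, end, side="right"))
        if n_eligible == 0:
            out.append(replace(t, onset_bin=end, matched_fallback=True))
        else:
            pick = int(rng.integers(0, n_eligible))
            out.append(
                replace(t, onset_bin=int(sorted_onsets[pick]), matched_fallback=False)
            )
    return out


def _require_onsets(trajectories: Iterable[Trajectory]) -> None:
    for t in trajectories:
        if t.onset_bin is None:
            raise ContractViolationError(
                f"stay {t.stay_id} has no onset bin; run assign_control_onsets first"
            )


def build_fixed_horizon(
    trajectories: Sequence[Trajectory], h: int, config: StrategyConfig | None = None
) -> EvaluationSample:
    """One record per stay: the score exactly ``h`` hours before onset.

    Stays with ``onset_bin < h`` (length of stay shorter than the horizon) are
    excluded and counted in ``n_excluded``.
    """
    if h is None or h < 1:
        raise ConfigurationError("h must be >= 1 for fixed-horizon evaluation")
    _require_onsets(trajectories)
    records, excluded = [], []
    for t in trajectories:
        b = t.onset_bin - h
        if b < 0:
            excluded.append(t.stay_id)
            continue
        records.append((t.stay_id, float(b), t.scores[b], int(t.is_sepsis), 1.0))
    return _as_record_sample(records, config, len(excluded), excluded)


def build_peak_score(
    trajectories: Sequence[Trajectory],
    h: int | None = None,
    config: StrategyConfig | None = None,
) -> EvaluationSample:
    """One record per stay: the maximum pre-onset score.

    With ``h`` absent the maximum runs over all bins before onset; with ``h``
    given it runs over the last ``h`` pre-onset bins, and stays shorter than the
    horizon are excluded.  The onset-bin prediction itself is never included.
    """
    _require_onsets(trajectories)
    records, excluded = [], []
    for t in trajectories:
        stop = t.onset_bin
        start = 0 if h is None else stop - h
        if start < 0 or stop - start == 0:
            excluded.append(t.stay_id)
            continue
        peak = float(np.max(t.scores[start:stop]))
        records.append((t.stay_id, np.nan, peak, int(t.is_sepsis), 1.0))
    return _as_record_sample(records, config, len(excluded), excluded)


def build_continuous(
    trajectories: Sequence[Trajectory], h: int, config: StrategyConfig | None = None
) -> EvaluationSample:
    """All pre-onset hourly scores; positives are case bins within ``h`` of onset.

    The horizon only determines labeling — no stay is excluded by it.  Each
    stay's records are weighted 1/n_i so the total weight equals the number of
    stays.
    """
    if h is None or h < 1:
        raise ConfigurationError("h must be >= 1 for continuous evaluation")
    _require_onsets(trajectories)
    sids, bins, yp, yt, w = [], [], [], [], []
    for t in trajectories:
        n = t.onset_bin  # records for bins 0 .. onset_bin - 1
        b = np.arange(n)
        labels = (
            ((b >= n - h) & (b < n)).astype(int) if t.is_sepsis else np.zeros(n, int)
        )
        sids.append(np.full(n, t.stay_id, dtype=object))
        bins.append(b.astype(float))
        yp.append(t.scores[:n])
        yt.append(labels)
        w.append(np.full(n, 1.0 / n))
    return EvaluationSample(
        stay_ids=np.concatenate(sids) if sids else np.asarray([], dtype=object),
        bins=np.concatenate(bins) if bins else np.asarray([], dtype=float),
        y_pred=np.concatenate(yp) if yp else np.asarray([], dtype=float),
        y_true=np.concatenate(yt) if yt else np.asarray([], dtype=int),
        weights=np.concatenate(w) if w else np.asarray([], dtype=float),
        config=config,
    )


def harmonize_prevalence(
    trajectories: Sequence[Trajectory], target_prevalence: float, seed: int
) -> list[Trajectory]:
    """Down-sample controls so the stay-level prevalence matches the target.

    Cases are never removed; controls are dropped uniformly at random (seeded,
    without replacement).  Raises :class:`ConfigurationError` if the cohort's
    prevalence already exceeds the target (down-sampling cases is out of
    contract).
    """
    if not (0 < target_prevalence < 1):
        raise ConfigurationError("target_prevalence must lie in (0, 1)")
    case_idx = [i for i, t in enumerate(trajectories) if t.is_sepsis]
    ctrl_idx = [i for i, t in enumerate(trajectories) if not t.is_sepsis]
    n_case = len(case_idx)
    if n_case == 0:
        raise ConfigurationError("cannot harmonize a cohort with no cases")
    k = int(round(n_case * (1.0 - target_prevalence) / target_prevalence))
    if k > len(ctrl_idx):
        raise ConfigurationError(
            f"cohort prevalence {n_case / len(trajectories):.4f} already exceeds "
            f"target {target_prevalence}; down-sampling cases is not supported"
        )
    rng = np.random.default_rng(seed)
    keep_ctrl = set(rng.choice(ctrl_idx, size=k, replace=False).tolist())
    keep = sorted(set(case_idx) | keep_ctrl)
    return [trajectories[i] for i in keep]


_BUILDERS: dict[str, Callable] = {
    "fixed_horizon": build_fixed_horizon,
    "peak_score": build_peak_score,
    "continuous": build_continuous,
}


def build_sample(
    trajectories: Sequence[Trajectory], config: StrategyConfig
) -> EvaluationSample:
    """Run the full design for one arm: harmonize, assign onsets, build records.

    Harmonization happens before onset assignment and before any horizon
    filtering, so all strategies see the same underlying patient set.
    """
    trajs = list(trajectories)
    if config.target_prevalence is not None:
        trajs = harmonize_prevalence(
            trajs, config.target_prevalence, derive_seed(config.seed, "harmonize")
        )
    match_seed = (
        derive_seed(config.seed, "matching") if config.onset_matching else None
    )
    trajs = assign_control_onsets(trajs, config.onset_matching, match_seed)
    if config.strategy == "peak_score":
        return build_peak_score(trajs, config.h, config)
    return _BUILDERS[config.strategy](trajs, config.h, config)
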