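"""Bootstrap uncertainty and paired significance testing for strategy contrasts.

The resampling unit is the ICU stay.  Onset matching and prevalence
harmonization are design steps frozen *before* bootstrapping: replicates
resample the observed sample's stays (with their already-assigned onsets and
weights), they never redraw the matching.  Because every builder is
deterministic per stay, gathering the observed records of a stay resample is
identical to rebuilding the sample from the resampled trajectories — the
implementation gathers, which keeps 10^5-replicate studies cheap.

The paired test follows the bootstrap Wald recipe: one shared stay resample per
replicate feeds both arms, the per-replicate AUROC difference is recorded, its
SD estimates the SE of the observed difference, and a two-sided p-value comes
from the standard normal.  Families of related contrasts are corrected with the
Holm step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import BootstrapError, ConfigurationError, UndefinedMetricError
from .evaluation import (
    EvaluationSample,
    StrategyConfig,
    Trajectory,
    assign_control_onsets,
    build_continuous,
    build_fixed_horizon,
    build_peak_score,
    build_sample,
    derive_seed,
    harmonize_prevalence,
)
from .metrics import _auroc, weighted_auroc


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one paired bootstrap Wald contrast between two arms."""

    contrast: tuple[str, str]
    delta_observed: float
    se_boot: float
    z: float
    p_raw: float
    p_holm: float | None
    B: int
    auroc_a: float
    auroc_b: float


class _StayGroups:
    """Contiguous per-stay record ranges of a sample, aligned to a stay universe.

    Builders emit records grouped by stay in trajectory order, so each stay's
    records form one contiguous slice; stays excluded from the sample get an
    empty slice.  ``gather(idx)`` returns the record indices of the stay
    resample ``idx`` fully vectorized.
    """

    def __init__(self, sample: EvaluationSample, universe: Sequence[str]):
        pos = {sid: i for i, sid in enumerate(universe)}
        n = len(universe)
        starts = np.zeros(n, dtype=np.int64)
        stops = np.zeros(n, dtype=np.int64)
        sids = sample.stay_ids
        i = 0
        while i < sids.size:
            j = i
            while j < sids.size and sids[j] == sids[i]:
                j += 1
            k = pos[sids[i]]
            starts[k], stops[k] = i, j
            i = j
        self.starts, self.stops = starts, stops
        self.sample = sample

    def gather(self, stay_idx: np.ndarray) -> np.ndarray:
        lengths = (self.stops - self.starts)[stay_idx]
        total = int(lengths.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64)
        cs = np.cumsum(lengths)
        offsets = np.arange(total, dtype=np.int64) - np.repeat(cs - lengths, lengths)
        return np.repeat(self.starts[stay_idx], lengths) + offsets

    def auroc(self, stay_idx: np.ndarray) -> float:
        rec = self.gather(stay_idx)
        s = self.sample
        y = s.y_true[rec]
        if y.size == 0 or y.min() == y.max():
            raise UndefinedMetricError("single-class bootstrap replicate")
        return _auroc(y, s.y_pred[rec], s.weights[rec])

    def subsample(self, stay_idx: np.ndarray) -> EvaluationSample:
        rec = self.gather(stay_idx)
        s = self.sample
        return _dc_replace(
            s,
            stay_ids=s.stay_ids[rec],
            bins=s.bins[rec],
            y_pred=s.y_pred[rec],
            y_true=s.y_true[rec],
            weights=s.weights[rec],
        )


def bootstrap_ci(
    sample_builder: Callable[[Sequence[Trajectory]], EvaluationSample],
    metric: Callable[[EvaluationSample], object],
    trajectories: Sequence[Trajectory],
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    max_undefined_frac: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Percentile bootstrap CI of ``metric`` under stay resampling.

    ``sample_builder`` maps (onset-assigned) trajectories to an evaluation
    sample; it is invoked once on the observed cohort, and replicates resample
    its stays with replacement.  Replicates on which the metric is undefined
    (single-class resamples) are dropped; if more than ``max_undefined_frac``
    of replicates fail, a :class:`BootstrapError` advises a larger cohort.
    """
    if B < 100:
        raise ConfigurationError("B must be >= 100 for a percentile interval")
    observed = sample_builder(trajectories)
    res = metric(observed)
    point = float(getattr(res, "value", res))
    universe = [t.stay_id for t in trajectories]
    groups = _StayGroups(observed, universe)
    rng = np.random.default_rng(seed)
    n = len(universe)
    values = []
    n_undefined = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            sub = groups.subsample(idx)
            r = metric(sub)
            values.append(float(getattr(r, "value", r)))
        except UndefinedMetricError:
            n_undefined += 1
    if n_undefined > max_undefined_frac * B:
        raise BootstrapError(
            f"metric undefined in {n_undefined}/{B} replicates; use a larger cohort"
        )
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, (float(lo), float(hi))


def _build_for(config: StrategyConfig, trajs: Sequence[Trajectory]) -> EvaluationSample:
    if config.strategy == "fixed_horizon":
        return build_fixed_horizon(trajs, config.h, config)
    if config.strategy == "peak_score":
        return build_peak_score(trajs, config.h, config)
    return build_continuous(trajs, config.h, config)


def paired_bootstrap_wald(
    trajectories: Sequence[Trajectory],
    config_a: StrategyConfig,
    config_b: StrategyConfig,
    B: int = 1000,
    seed: int = 0,
    max_undefined_frac: float = 0.05,
) -> PairedTestResult:
    """Paired bootstrap Wald test of the AUROC difference between two arms.

    Harmonization and onset matching are performed once on the observed cohort
    (shared between arms wherever their settings agree, using seeds derived
    from ``seed``); each replicate then draws one stay resample that feeds both
    arms, and ``z = delta_observed / SD(delta_replicates)``.

    The two configs must agree on ``target_prevalence`` so that both arms see
    the same patient universe.
    """
    if config_a.target_prevalence != config_b.target_prevalence:
        raise ConfigurationError(
            "paired test requires identical target_prevalence in both configs"
        )
    trajs = list(trajectories)
    if config_a.target_prevalence is not None:
        trajs = harmonize_prevalence(
            trajs, config_a.target_prevalence, derive_seed(seed, "harmonize")
        )
    assigned: dict[bool, list[Trajectory]] = {}
    for matching in {config_a.onset_matching, config_b.onset_matching}:
        assigned[matching] = assign_control_onsets(
            trajs, matching, derive_seed(seed, "matching") if matching else None
        )
    sample_a = _build_for(config_a, assigned[config_a.onset_matching])
    sample_b = _build_for(config_b, assigned[config_b.onset_matching])

    universe = [t.stay_id for t in trajs]
    ga = _StayGroups(sample_a, universe)
    gb = _StayGroups(sample_b, universe)
    auroc_a = weighted_auroc(sample_a).value
    auroc_b = weighted_auroc(sample_b).value
    delta_obs = auroc_a - auroc_b

    rng = np.random.default_rng(derive_seed(seed, "bootstrap"))
    n = len(universe)
    deltas = []
    n_undefined = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            deltas.append(ga.auroc(idx) - gb.auroc(idx))
        except UndefinedMetricError:
            n_undefined += 1
    if n_undefined > max_undefined_frac * B:
        raise BootstrapError(
            f"AUROC undefined in {n_undefined}/{B} replicates; use a larger cohort"
        )
    deltas = np.asarray(deltas)
    se = float(np.std(deltas, ddof=1))
    if se == 0.0:
        z = 0.0 if delta_obs == 0.0 else np.inf * np.sign(delta_obs)
    else:
        z = delta_obs / se
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if se == 0.0 and delta_obs == 0.0:
        p = 1.0

    def _name(c: StrategyConfig) -> str:
        h = "" if c.h is None else f"_h{c.h}"
        m = "matched" if c.onset_matching else "unmatched"
        return f"{c.strategy}{h}_{m}"

    return PairedTestResult(
        contrast=(_name(config_a), _name(config_b)),
        delta_observed=float(delta_obs),
        se_boot=se,
        z=float(z),
        p_raw=min(1.0, p),
        p_holm=None,
        B=B,
        auroc_a=float(auroc_a),
        auroc_b=float(auroc_b),
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def adjust_family(results: Sequence[PairedTestResult]) -> list[PairedTestResult]:
    """Attach Holm-adjusted p-values to a family of related contrasts."""
    adj = holm_adjust([r.p_raw for r in results])
    return [_dc_replace(r, p_holm=float(a)) for r, a in zip(results, adj)]
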