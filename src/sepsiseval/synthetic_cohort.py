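"""Seeded synthetic ICU cohorts at two fidelity levels.

The evaluation framework is exercised end to end on simulated data with the
statistical structure the analysis assumes, at two levels:

* **score cohorts** — per-stay hourly risk-score trajectories with a rising
  pre-onset signal for cases, stationary AR(1) noise, and an optional
  pre-discharge risk decline for controls.  These drive the evaluation, metric,
  and inference modules.
* **raw EHR-like cohorts** — irregular time-stamped measurements with planted
  out-of-range outliers, antibiotic dose events, and step-changing SOFA series.
  These drive the Sepsis-3 labeler and the preprocessing pipeline, with full
  bookkeeping of the planted truth so recovery can be tested.

Defaults encode the intended study conditions: ~10% sepsis prevalence,
log-normal control length of stay (median 24 h), log-normal onset times
(median 30 h) so that septic stays are longer than control stays on average,
stays truncated at 7 days, and onsets only after the first hours of admission.

Case score trajectories end at the onset bin (every evaluation strategy
discards post-onset predictions, so later scores would be dead weight); the
raw-EHR level keeps post-onset data because SOFA after onset exists there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError
from .evaluation import Trajectory
from .labeling import SepsisLabel

MAX_STAY_H = 168.0  # 7-day truncation
MIN_ONSET_H = 5.0   # cohort rule excludes onsets < 4 h; generate with margin
MIN_LOS_H = 6.0     # eligibility requires >= 6 h of data


@dataclass(frozen=True)
class DistSpec:
    """A small distribution spec (family + parameters, hours).

    Families: ``lognormal`` (params ``median``, ``sigma``), ``uniform``
    (``low``, ``high``), ``constant`` (``value``), ``gamma`` (``shape``,
    ``scale``).
    """

    family: str
    params: dict = field(default_factory=dict)

    def validate(self, field_name: str) -> None:
        p = self.params
        ok = {
            "lognormal": lambda: p.get("median", 0) > 0 and p.get("sigma", -1) >= 0,
            "uniform": lambda: 0 < p.get("low", -1) <= p.get("high", -1),
            "constant": lambda: p.get("value", 0) > 0,
            "gamma": lambda: p.get("shape", 0) > 0 and p.get("scale", 0) > 0,
        }
        if self.family not in ok:
            raise ConfigurationError(
                f"{field_name}: unknown distribution family {self.family!r}"
            )
        if not ok[self.family]():
            raise ConfigurationError(
                f"{field_name}: invalid parameters {p} for family {self.family!r}"
            )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "lognormal":
            return rng.lognormal(np.log(p["median"]), p["sigma"], size)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.family == "constant":
            return np.full(size, float(p["value"]))
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size)
        raise ConfigurationError(f"unknown distribution family {self.family!r}")

    def median(self) -> float:
        p = self.params
        if self.family == "lognormal":
            return float(p["median"])
        if self.family == "uniform":
            return 0.5 * (p["low"] + p["high"])
        if self.family == "constant":
            return float(p["value"])
        if self.family == "gamma":
            from scipy.stats import gamma as _gamma
            return float(_gamma(a=p["shape"], scale=p["scale"]).median())
        raise ConfigurationError(f"unknown distribution family {self.family!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "DistSpec":
        d = dict(d)
        return cls(family=d.pop("family"), params=d)


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort generator.

    Durations are in hours; ``signal_gain``, ``noise_sd`` and
    ``discharge_recovery`` act on the latent logit scale before the sigmoid
    squashing.  The same config and seed always produce a bit-identical cohort.
    """

    n_stays: int = 1000
    prevalence: float = 0.10
    los_control: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"median": 24.0, "sigma": 0.8})
    )
    onset_time: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"median": 30.0, "sigma": 0.7})
    )
    post_onset_stay: DistSpec = field(
        default_factory=lambda: DistSpec("lognormal", {"median": 48.0, "sigma": 0.6})
    )
    signal_lead: float = 12.0
    signal_gain: float = 2.0
    noise_rho: float = 0.7
    noise_sd: float = 0.5
    discharge_recovery: float = 0.0
    baseline_logit: float = -1.0
    seed: int = 0
    # raw-EHR level only: planted confusers and measurement corruption
    control_short_abx_frac: float = 0.25
    control_sofa_step_frac: float = 0.25
    outlier_frac: float = 0.01
    non_icu_frac: float = 0.0
    minor_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_stays < 1:
            raise ConfigurationError("n_stays must be >= 1")
        if not (0 < self.prevalence < 1):
            raise ConfigurationError("prevalence must lie strictly in (0, 1)")
        if not (0 <= self.noise_rho < 1):
            raise ConfigurationError("noise_rho must lie in [0, 1)")
        for name in ("signal_lead", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("signal_gain", "discharge_recovery", "outlier_frac",
                     "control_short_abx_frac", "control_sofa_step_frac",
                     "non_icu_frac", "minor_frac"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("los_control", "onset_time", "post_onset_stay"):
            getattr(self, name).validate(name)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for name in ("los_control", "onset_time", "post_onset_stay"):
            if name in d and isinstance(d[name], dict):
                d[name] = DistSpec.from_dict(d[name])
        return cls(**d)


@dataclass
class ScoreCohort:
    """Score-level cohort: one trajectory and one label per stay."""

    trajectories: list[Trajectory]
    labels: list[SepsisLabel]

    @property
    def n_cases(self) -> int:
        return sum(t.is_sepsis for t in self.trajectories)

    @property
    def n_stays(self) -> int:
        return len(self.trajectories)


@dataclass
class RawStay:
    """One ICU stay's raw event streams (times in hours since admission)."""

    stay_id: str
    age: float
    sex: str
    height: float
    weight: float
    measurements: list[tuple[str, float, float]]  # (feature, time_h, value)
    abx_events: list[tuple[str, float]]           # (drug id, time_h)
    sofa_series: list[tuple[float, int]]          # (time_h, score)
    admission_origin: str = "icu"


@dataclass
class EhrCohort:
    """Raw-EHR cohort plus the planted ground truth for recovery tests."""

    stays: list[RawStay]
    truth: pd.DataFrame          # stay_id, is_sepsis, t_si, t_onset
    n_outliers_planted: int
    n_measurements: int


def _truncated(rng, spec: DistSpec, size: int, lo: float, hi: float) -> np.ndarray:
    """Rejection-sample ``spec`` into [lo, hi]; falls back to clipping if stuck."""
    out = spec.sample(rng, size)
    for _ in range(200):
        bad = (out < lo) | (out > hi)
        if not np.any(bad):
            return out
        out[bad] = spec.sample(rng, int(bad.sum()))
    return np.clip(out, lo, hi)


def _ar1(rng, n_rows: int, n_cols: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise, one series per row."""
    eps = rng.standard_normal((n_rows, n_cols))
    x = np.empty_like(eps)
    x[:, 0] = sd * eps[:, 0]
    c = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n_cols):
        x[:, t] = rho * x[:, t - 1] + c * eps[:, t]
    return x


def generate_score_cohort(config: CohortConfig) -> ScoreCohort:
    """Simulate hourly risk-score trajectories for a two-group cohort.

    Case latent risk at bin t is ``baseline + signal_gain * max(0, 1 -
    (t_onset - t)/signal_lead) + AR(1)``, squashed to (0, 1) by a sigmoid;
    control risk is ``baseline + AR(1) - discharge_recovery * ramp`` with the
    ramp rising over the final ``signal_lead`` hours before the last bin.
    Onset times are drawn from ``onset_time`` truncated to [5 h, 168 h];
    control stay lengths from ``los_control`` truncated to [6 h, 168 h].
    Case trajectories end at the onset bin; controls at the last data bin with
    ``onset_bin`` left unset until an onset policy assigns one.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_stays
    is_case = rng.random(n) < config.prevalence
    onset_h = _truncated(rng, config.onset_time, n, MIN_ONSET_H, MAX_STAY_H)
    los_h = _truncated(rng, config.los_control, n, MIN_LOS_H, MAX_STAY_H)

    onset_bin = np.floor(onset_h).astype(int)
    n_bins = np.where(is_case, onset_bin + 1, np.floor(los_h).astype(int))
    n_bins = np.clip(n_bins, 1, int(MAX_STAY_H))
    max_len = int(n_bins.max())
    noise = _ar1(rng, n, max_len, config.noise_rho, config.noise_sd)
    t_grid = np.arange(max_len)

    trajectories: list[Trajectory] = []
    labels: list[SepsisLabel] = []
    for i in range(n):
        L = int(n_bins[i])
        t = t_grid[:L]
        latent = config.baseline_logit + noise[i, :L]
        if is_case[i]:
            ramp = np.maximum(0.0, 1.0 - (onset_h[i] - t) / config.signal_lead)
            latent = latent + config.signal_gain * ramp
        elif config.discharge_recovery > 0:
            last = L - 1
            ramp = np.maximum(0.0, 1.0 - (last - t) / config.signal_lead)
            latent = latent - config.discharge_recovery * ramp
        sid = f"s{i:05d}"
        trajectories.append(
            Trajectory(
                stay_id=sid,
                scores=expit(latent),
                is_sepsis=bool(is_case[i]),
                onset_bin=int(onset_bin[i]) if is_case[i] else None,
            )
        )
        labels.append(
            SepsisLabel(
                stay_id=sid,
                is_sepsis=bool(is_case[i]),
                t_onset=float(onset_h[i]) if is_case[i] else None,
            )
        )
    return ScoreCohort(trajectories=trajectories, labels=labels)


# ---------------------------------------------------------------------------
# raw EHR level
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    name: str
    mean: float
    sd: float
    rate_per_h: float  # expected measurements per hour


def _default_features() -> tuple[FeatureSpec, ...]:
    vitals = [
        ("heart_rate", 80, 15, 1.0), ("sys_bp", 120, 20, 1.0),
        ("dia_bp", 65, 12, 1.0), ("mean_arterial_pressure", 80, 12, 1.0),
        ("resp_rate", 18, 5, 1.0), ("temperature", 37.0, 0.7, 0.5),
        ("o2_saturation", 96, 3, 1.0), ("fio2", 0.4, 0.12, 0.5),
    ]
    labs = [
        ("lactate", 1.8, 1.0), ("wbc", 9, 4), ("creatinine", 1.1, 0.6),
        ("bilirubin", 0.8, 0.5), ("platelets", 220, 80), ("glucose", 130, 40),
        ("sodium", 139, 4), ("potassium", 4.1, 0.5), ("hemoglobin", 11, 2),
        ("ph", 7.38, 0.06), ("pco2", 40, 8), ("po2", 90, 25),
        ("bicarbonate", 24, 4), ("urea", 20, 10), ("crp", 40, 30),
        ("albumin", 3.4, 0.6), ("calcium", 8.8, 0.7), ("magnesium", 2.0, 0.3),
        ("phosphate", 3.4, 0.8), ("chloride", 104, 5), ("inr", 1.2, 0.3),
        ("ptt", 32, 8), ("fibrinogen", 350, 100), ("troponin", 0.05, 0.04),
        ("creatine_kinase", 150, 120), ("alt", 40, 30), ("ast", 45, 35),
        ("ggt", 60, 40), ("lipase", 40, 25), ("amylase", 60, 30),
        ("urine_output", 80, 40), ("base_excess", 0.0, 3.0),
        ("anion_gap", 12, 3), ("neutrophils", 70, 10), ("lymphocytes", 20, 8),
        ("monocytes", 7, 3), ("eosinophils", 2, 1.5), ("mcv", 90, 6),
        ("mch", 30, 2.5), ("rdw", 14, 2),
    ]
    out = [FeatureSpec(n, m, s, r) for n, m, s, r in vitals]
    out += [FeatureSpec(n, m, s, 0.25) for n, m, s in labs]
    assert len(out) == 48
    return tuple(out)


DEFAULT_FEATURES: tuple[FeatureSpec, ...] = _default_features()
STATIC_FEATURES: tuple[str, ...] = ("age", "sex", "height", "weight")


def default_plausibility_ranges() -> pd.DataFrame:
    """Physiological plausibility bounds for the synthetic features.

    Bounds are placed at mean +/- 6 sd (floored at 0 for non-negative
    quantities), wide enough that in-range simulated values essentially never
    touch them while planted outliers always lie outside.
    """
    rows = [
        {
            "feature": f.name,
            "lower": max(0.0, f.mean - 6 * f.sd) if f.name != "base_excess"
            else f.mean - 6 * f.sd,
            "upper": f.mean + 6 * f.sd,
        }
        for f in DEFAULT_FEATURES
    ]
    return pd.DataFrame(rows)


def generate_ehr_cohort(config: CohortConfig) -> EhrCohort:
    """Simulate raw EHR-like stays sufficient to drive the Sepsis-3 labeler.

    Cases receive a sustained antibiotic course (doses every <= 20 h spanning
    >= 72 h) starting shortly before the planted onset, and a SOFA step of
    >= 2 points exactly at the onset time inside the SI window.  A configurable
    fraction of controls receive short (< 3-day) antibiotic courses and/or SOFA
    steps outside any SI window, so labeler specificity is exercised.
    Measurements are emitted as per-feature Poisson processes; a configurable
    fraction is replaced by values outside the plausibility bounds, counted in
    the returned bookkeeping.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x5EED]))
    n = config.n_stays
    is_case = rng.random(n) < config.prevalence
    ranges = default_plausibility_ranges().set_index("feature")

    stays: list[RawStay] = []
    truth_rows = []
    n_outliers = 0
    n_meas = 0
    for i in range(n):
        sid = f"e{i:05d}"
        age = float(rng.uniform(18, 90))
        if config.minor_frac > 0 and rng.random() < config.minor_frac:
            age = float(rng.uniform(2, 17))
        origin = "icu"
        if config.non_icu_frac > 0 and rng.random() < config.non_icu_frac:
            origin = "ward"
        sex = "f" if rng.random() < 0.45 else "m"
        height = float(rng.normal(172, 10))
        weight = float(rng.normal(80, 16))

        abx: list[tuple[str, float]] = []
        t_si = t_onset = None
        if is_case[i]:
            # onset capped so a full >= 72 h course fits before the 7-day cut
            t_onset = float(_truncated(rng, config.onset_time, 1, MIN_ONSET_H, 90.0)[0])
            t_si = max(0.0, t_onset - float(rng.uniform(0.0, 24.0)))
            span = min(72.0 + float(rng.uniform(2.0, 48.0)), MAX_STAY_H - t_si)
            t = t_si
            while t <= t_si + span:
                abx.append(("abx_a", round(t, 2)))
                t += float(rng.uniform(8.0, 20.0))
            if abx[-1][1] - t_si < 72.0:       # guarantee the 3-day span
                abx.append(("abx_a", round(t_si + span, 2)))
            post = float(config.post_onset_stay.sample(rng, 1)[0])
            los = min(MAX_STAY_H, max(t_onset + post, abx[-1][1] + 1.0))
        else:
            los = float(_truncated(rng, config.los_control, 1, MIN_LOS_H, MAX_STAY_H)[0])
            if rng.random() < config.control_short_abx_frac:
                # short course: gaps <= 24 h but span < 72 h -> no SI
                t0 = float(rng.uniform(0, max(1.0, los - 45)))
                for k in range(3):
                    tt = t0 + 20.0 * k
                    if tt < los:
                        abx.append(("abx_a", round(tt, 2)))
            if rng.random() < 0.15 and los > 40:
                # an isolated late dose, > 24 h from anything else
                last = abx[-1][1] if abx else -np.inf
                tt = max(last + 30.0, los - 5.0)
                if tt < los:
                    abx.append(("abx_a", round(tt, 2)))

        # SOFA: step-changing integer series every ~4 h
        sofa_times = np.arange(2.0, max(los, 6.0), 4.0)
        base = int(rng.integers(0, 4))
        sofa_vals = base + (rng.random(sofa_times.size) < 0.3).astype(int)
        if is_case[i]:
            # pre-onset SOFA held at the baseline so the planted step is the
            # first >= 2-point rise the labeler can see
            step = int(rng.integers(2, 5))
            sofa_times = np.sort(np.append(sofa_times, t_onset))
            sofa_vals = np.full(sofa_times.size, base)
            post_mask = sofa_times >= t_onset
            sofa_vals = np.where(post_mask, base + step, sofa_vals)
        elif rng.random() < config.control_sofa_step_frac:
            # confuser: a >= 2-point step, harmless without an SI window
            j = int(rng.integers(0, sofa_times.size))
            sofa_vals[j:] = base + 2
        sofa_series = [(float(t), int(v)) for t, v in zip(sofa_times, sofa_vals)]

        measurements: list[tuple[str, float, float]] = []
        for f in DEFAULT_FEATURES:
            k = rng.poisson(f.rate_per_h * los)
            if f.rate_per_h >= 1.0:
                k = max(k, int(los))  # vitals: at least hourly, keeps gaps < 12 h
            times = np.sort(rng.uniform(0, los, k))
            lo = float(ranges.loc[f.name, "lower"])
            hi = float(ranges.loc[f.name, "upper"])
            vals = np.clip(rng.normal(f.mean, f.sd, k), lo + 1e-9, hi - 1e-9)
            out_mask = rng.random(k) < config.outlier_frac
            vals[out_mask] = hi + f.sd * (1.0 + np.abs(rng.standard_normal(
                int(out_mask.sum()))))
            n_outliers += int(out_mask.sum())
            n_meas += k
            measurements.extend(
                (f.name, float(t), float(v)) for t, v in zip(times, vals)
            )
        measurements.sort(key=lambda m: m[1])

        stays.append(
            RawStay(
                stay_id=sid, age=age, sex=sex, height=height, weight=weight,
                measurements=measurements, abx_events=abx,
                sofa_series=sofa_series, admission_origin=origin,
            )
        )
        truth_rows.append(
            {
                "stay_id": sid,
                "is_sepsis": bool(is_case[i]),
                "t_si": t_si,
                "t_onset": t_onset,
            }
        )
    return EhrCohort(
        stays=stays,
        truth=pd.DataFrame(truth_rows),
        n_outliers_planted=n_outliers,
        n_measurements=n_meas,
    )
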