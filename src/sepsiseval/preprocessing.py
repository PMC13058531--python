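"""Irregular EHR streams -> hourly model-ready matrices -> feature tables.

The pipeline mirrors common ICU modeling practice: implausible values are
removed against a supplied per-feature range table, remaining measurements are
binned into hourly intervals by their median, missing bins are forward-filled
within the stay with a per-channel fallback mean for leading gaps, and binary
missingness indicators (one per time-varying and static channel) record which
bins were actually observed.

For a penalized logistic baseline, trailing-window summary statistics (min,
max, mean, median, population variance over the last 4, 8 and 16 hours) are
added per channel: with 48 time-varying channels, 3 windows and 5 statistics
plus 4 static channels this yields 48 + 48*5*3 + 4 = 772 columns.

Bin convention: 0-based, bin t covers [t, t+1) hours since admission; a score
"at bin t" may use data through bin t inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, ContractViolationError
from .synthetic_cohort import DEFAULT_FEATURES, STATIC_FEATURES, RawStay

TEMPORAL_WINDOWS = (4, 8, 16)
TEMPORAL_STATS = ("min", "max", "mean", "median", "variance")


@dataclass(frozen=True)
class PlausibilityRange:
    feature: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"plausibility range for {self.feature}: lower must be < upper"
            )


@dataclass
class HourlyMatrix:
    """One stay's hourly-binned channels with an observed mask.

    ``values[t, c]`` is the median of channel ``c``'s raw measurements in hour
    bin t (NaN if none); ``mask[t, c]`` is True iff at least one raw
    measurement fell in that bin.  Statics are carried alongside.
    """

    stay_id: str
    values: np.ndarray        # (n_bins, n_channels), NaN = missing
    mask: np.ndarray          # (n_bins, n_channels) bool
    feature_names: tuple[str, ...]
    statics: np.ndarray       # (n_statics,), NaN = missing
    static_names: tuple[str, ...] = STATIC_FEATURES
    static_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.static_mask is None:
            self.static_mask = ~np.isnan(self.statics)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def measurements_frame(stays: Iterable[RawStay]) -> pd.DataFrame:
    """Long-format measurement table (stay_id, name, time_h, value)."""
    rows = [
        (s.stay_id, name, t, v)
        for s in stays
        for name, t, v in s.measurements
    ]
    return pd.DataFrame(rows, columns=["stay_id", "name", "time_h", "value"])


def filter_plausibility(
    measurements: pd.DataFrame,
    ranges: pd.DataFrame,
    exempt: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop values outside the per-feature [lower, upper] ranges (inclusive).

    ``ranges`` has columns (feature, lower, upper).  Every measured feature
    must either have a range or be listed in ``exempt``; otherwise a
    :class:`ConfigurationError` names the feature.  Returns the kept
    measurements and a per-feature removal log.
    """
    rng = ranges.set_index("feature")
    for f, lo, hi in rng[["lower", "upper"]].itertuples():
        if not lo < hi:
            raise ConfigurationError(f"plausibility range for {f}: lower must be < upper")
    measured = set(measurements["name"].unique())
    uncovered = measured - set(rng.index) - set(exempt)
    if uncovered:
        raise ConfigurationError(
            f"no plausibility range for feature(s): {sorted(uncovered)[:5]}"
        )
    lo = measurements["name"].map(rng["lower"])
    hi = measurements["name"].map(rng["upper"])
    keep = measurements["name"].isin(exempt) | (
        (measurements["value"] >= lo) & (measurements["value"] <= hi)
    )
    removed = measurements.loc[~keep]
    log = (
        removed.groupby("name").size().rename("n_removed").reset_index()
        .rename(columns={"name": "feature"})
    )
    return measurements.loc[keep].reset_index(drop=True), log


def aggregate_hourly(
    stay: RawStay | pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    n_bins: int | None = None,
    stay_id: str | None = None,
) -> HourlyMatrix:
    """Median-aggregate one stay's measurements into hourly bins.

    Accepts a :class:`RawStay` or a long-format frame (name, time_h, value).
    ``n_bins`` defaults to ``floor(max time) + 1`` so the last observed
    measurement falls in the final bin.
    """
    if feature_names is None:
        feature_names = tuple(f.name for f in DEFAULT_FEATURES)
    if isinstance(stay, RawStay):
        df = pd.DataFrame(stay.measurements, columns=["name", "time_h", "value"])
        statics = np.asarray(
            [stay.age, 0.0 if stay.sex == "m" else 1.0, stay.height, stay.weight]
        )
        stay_id = stay.stay_id
    else:
        df = stay
        statics = np.full(len(STATIC_FEATURES), np.nan)
        if stay_id is None:
            stay_id = "?"
    if len(df) and (df["time_h"] < 0).any():
        raise ContractViolationError("measurement times must be >= 0")
    if n_bins is None:
        n_bins = int(np.floor(df["time_h"].max())) + 1 if len(df) else 1

    c_index = {name: j for j, name in enumerate(feature_names)}
    values = np.full((n_bins, len(feature_names)), np.nan)
    mask = np.zeros((n_bins, len(feature_names)), dtype=bool)
    if len(df):
        df = df[df["name"].isin(c_index)].copy()
        df["bin"] = np.floor(df["time_h"]).astype(int)
        df = df[df["bin"] < n_bins]
        med = df.groupby(["name", "bin"])["value"].median()
        for (name, b), v in med.items():
            j = c_index[name]
            values[b, j] = v
            mask[b, j] = True
    return HourlyMatrix(
        stay_id=stay_id, values=values, mask=mask,
        feature_names=tuple(feature_names), statics=statics,
    )


def impute(
    matrix: HourlyMatrix, fallback_means: Mapping[str, float]
) -> tuple[HourlyMatrix, np.ndarray]:
    """Forward-fill within the stay; leading gaps get the fallback mean.

    Returns the densified matrix plus the per-bin indicator channels: one
    binary column per time-varying channel (equal to the observed mask) and
    one per static, replicated across bins.  A channel needing a fallback
    without one configured raises :class:`ConfigurationError`.
    """
    df = pd.DataFrame(matrix.values, columns=list(matrix.feature_names))
    filled = df.ffill()
    for name in matrix.feature_names:
        if filled[name].isna().any():
            if name not in fallback_means:
                raise ConfigurationError(f"no fallback mean configured for {name}")
            filled[name] = filled[name].fillna(fallback_means[name])
    statics = matrix.statics.copy()
    for j, name in enumerate(matrix.static_names):
        if np.isnan(statics[j]):
            if name not in fallback_means:
                raise ConfigurationError(f"no fallback mean configured for {name}")
            statics[j] = fallback_means[name]
    static_ind = np.repeat(
        matrix.static_mask.astype(float)[None, :], matrix.n_bins, axis=0
    )
    indicators = np.hstack([matrix.mask.astype(float), static_ind])
    dense = replace(matrix, values=filled.to_numpy(), statics=statics)
    return dense, indicators


def engineer_temporal_features(
    matrix: HourlyMatrix,
    windows: Sequence[int] = TEMPORAL_WINDOWS,
    stats: Sequence[str] = TEMPORAL_STATS,
) -> pd.DataFrame:
    """Trailing-window statistics on a dense hourly matrix.

    Window ``w`` at bin t covers the last ``min(w, t + 1)`` bins ending at t
    inclusive (truncated at the stay start).  Variance uses the population
    convention (ddof 0), so single-value windows give 0.  Columns: the raw
    channels, then ``{name}_w{w}_{stat}``, then the statics replicated per
    bin — ``c * (1 + |stats| * |windows|) + n_statics`` columns in total
    (772 for the default 48 channels and 4 statics).
    """
    if np.isnan(matrix.values).any():
        raise ContractViolationError("temporal features require a dense (imputed) matrix")
    df = pd.DataFrame(matrix.values, columns=list(matrix.feature_names))
    parts = [df]
    agg = {
        "min": lambda r: r.min(),
        "max": lambda r: r.max(),
        "mean": lambda r: r.mean(),
        "median": lambda r: r.median(),
        "variance": lambda r: r.var(ddof=0),
    }
    for name in matrix.feature_names:
        for w in windows:
            roll = df[name].rolling(window=w, min_periods=1)
            for stat in stats:
                parts.append(
                    agg[stat](roll).rename(f"{name}_w{w}_{stat}")
                )
    static_df = pd.DataFrame(
        np.repeat(matrix.statics[None, :], matrix.n_bins, axis=0),
        columns=list(matrix.static_names),
    )
    parts.append(static_df)
    keys = pd.DataFrame(
        {"stay_id": matrix.stay_id, "bin": np.arange(matrix.n_bins)}
    )
    return pd.concat([keys] + parts, axis=1)


def cohort_feature_table(matrices: Sequence[HourlyMatrix], **kwargs) -> pd.DataFrame:
    """Stack per-stay feature tables into one cohort table."""
    return pd.concat(
        [engineer_temporal_features(m, **kwargs) for m in matrices],
        ignore_index=True,
    )


def fit_baseline_scorer(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Cross-validated ridge-penalized logistic scores for held-out stays.

    ``features`` is a cohort feature table with ``stay_id`` and ``bin``
    columns; ``labels`` is the aligned per-(stay, bin) binary target.  Stays
    are shuffled (seeded) and split into ``folds`` groups at the patient
    level; each fold's model is an L2 logistic regression with class weights
    inversely proportional to class frequencies, and scores in (0, 1) are
    emitted only for held-out stays.  A training fold containing a single
    class raises :class:`ConfigurationError` advising a larger cohort.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(features):
        raise ContractViolationError("labels must align with the feature table rows")
    stay_ids = features["stay_id"].to_numpy()
    x = features.drop(columns=["stay_id", "bin"]).to_numpy(dtype=float)
    stays = pd.unique(stay_ids)
    if stays.size < folds:
        raise ConfigurationError(f"need >= {folds} stays for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(stays.size)
    fold_of = {stays[j]: i % folds for i, j in enumerate(perm)}
    fold_idx = np.asarray([fold_of[s] for s in stay_ids])

    scores = np.full(len(features), np.nan)
    for k in range(folds):
        test = fold_idx == k
        train = ~test
        y_tr = labels[train]
        if y_tr.min() == y_tr.max():
            raise ConfigurationError(
                f"training fold {k} contains one class only; use a larger cohort"
            )
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=C, class_weight="balanced", max_iter=2000),
        )
        model.fit(x[train], y_tr)
        scores[test] = model.predict_proba(x[test])[:, 1]
    return pd.DataFrame(
        {"stay_id": stay_ids, "bin": features["bin"].to_numpy(), "score": scores}
    )


def inverse_frequency_weights(labels: np.ndarray) -> np.ndarray:
    """Per-record class weights proportional to 1/p for positives, 1/(1-p) else."""
    labels = np.asarray(labels, dtype=int)
    p = labels.mean()
    if p in (0.0, 1.0):
        raise ConfigurationError("class weights undefined for a single-class sample")
    return np.where(labels == 1, 1.0 / p, 1.0 / (1.0 - p))
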