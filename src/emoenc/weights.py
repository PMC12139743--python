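"""Encoding-weight analysis: fold pooling, emotion-class aggregation and
weight-versus-age correlation.

The 144 lagged ridge coefficients (48 features x 3 lags, per CV fold)
are reduced to 48 per-feature magnitudes by averaging absolute values
over folds and lags; the absolute value deliberately ignores whether a
feature maps to an HFB increase or decrease.  Per-feature magnitudes of
participants whose encoding is individually significant are then
correlated with age, ranked, and aggregated over the complex and basic
emotion classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .encoding import EncodingResult
from .errors import DegenerateDataError
from .features import EmotionFeatureSet

__all__ = [
    "WeightProfile",
    "WeightAgeResult",
    "pool_fold_weights",
    "aggregate_emotion_classes",
    "filter_significant",
    "weight_age_correlation",
]


@dataclass
class WeightProfile:
    """Per-participant pooled absolute feature weights."""

    participant: str
    age: float
    weights_abs: np.ndarray   # [n_features], >= 0

    def __post_init__(self) -> None:
        if np.any(self.weights_abs < 0):
            raise ValueError("pooled weights must be non-negative")


@dataclass
class WeightAgeResult:
    """Per-feature and aggregate weight-age Pearson correlations."""

    table: pd.DataFrame       # feature, r, p, class; ranked by r descending
    complex_r: float
    complex_p: float
    basic_r: float
    basic_p: float
    excluded: list[str]       # features with undefined (zero-variance) r


def pool_fold_weights(
    result: EncodingResult,
    feature_names,
    n_lags: int,
    reduce: str = "mean",
) -> np.ndarray:
    """Collapse [k_folds x (n_features * n_lags)] coefficients to one
    pooled magnitude per feature.

    Absolute values are averaged over folds and over lags (``reduce``
    may be 'max' to take the largest lag magnitude instead).  Columns
    are lag-major, matching the design matrix.
    """
    names = list(feature_names)
    n_feat = len(names)
    W = np.asarray(result.fold_weights, float)
    if W.ndim != 2 or W.shape[1] != n_feat * n_lags:
        raise ValueError(
            f"expected fold weights with {n_feat * n_lags} columns, got {W.shape}"
        )
    # [k x n_lags x n_feat] -> abs -> mean over folds, reduce over lags
    cube = np.abs(W.reshape(W.shape[0], n_lags, n_feat)).mean(axis=0)
    if reduce == "mean":
        return cube.mean(axis=0)
    if reduce == "max":
        return cube.max(axis=0)
    raise ValueError(f"unknown lag reduction {reduce!r}")


def aggregate_emotion_classes(
    profile: WeightProfile, feature_set: EmotionFeatureSet
) -> tuple[float, float]:
    """(complex mean, basic mean) of the pooled per-feature weights."""
    if len(profile.weights_abs) != feature_set.n_features:
        raise ValueError("profile length must match the feature vocabulary")
    cx = feature_set.indices(feature_set.complex_set)
    ba = feature_set.indices(feature_set.basic_set)
    return (
        float(profile.weights_abs[cx].mean()),
        float(profile.weights_abs[ba].mean()),
    )


def filter_significant(
    profiles: list[WeightProfile], p_values: dict[str, float], alpha: float = 0.05
) -> list[WeightProfile]:
    """Keep profiles whose encoding accuracy is individually significant
    (permutation p < alpha) — the inclusion rule of the weight analysis."""
    return [p for p in profiles if p_values[p.participant] < alpha]


def weight_age_correlation(
    profiles: list[WeightProfile], feature_set: EmotionFeatureSet
) -> WeightAgeResult:
    """Pearson correlation of each feature's pooled weight with age,
    ranked from largest to smallest, plus the complex/basic aggregate
    correlations (computed on aggregated weights, not by averaging
    per-feature correlations).  P-values are uncorrected.
    """
    if len(profiles) < 3:
        raise ValueError("need at least three participants")
    ages = np.array([p.age for p in profiles])
    if np.std(ages) == 0:
        raise DegenerateDataError("constant ages: correlation undefined")
    W = np.vstack([p.weights_abs for p in profiles])   # [n x 48]
    rows, excluded = [], []
    for j, name in enumerate(feature_set.names):
        col = W[:, j]
        if np.std(col) == 0:
            excluded.append(name)
            continue
        r, p = sps.pearsonr(col, ages)
        rows.append(
            {"feature": name, "r": float(r), "p": float(p),
             "class": feature_set.feature_class(name)}
        )
    if excluded:
        warnings.warn(
            f"excluding zero-variance features from ranking: {excluded}",
            RuntimeWarning,
        )
    table = pd.DataFrame(rows, columns=["feature", "r", "p", "class"])
    table = table.sort_values(
        "r", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)

    aggregates = np.array(
        [aggregate_emotion_classes(p, feature_set) for p in profiles]
    )
    def _corr(col: np.ndarray) -> tuple[float, float]:
        if np.std(col) == 0:
            return float("nan"), float("nan")
        r, p = sps.pearsonr(col, ages)
        return float(r), float(p)

    cx_r, cx_p = _corr(aggregates[:, 0])
    ba_r, ba_p = _corr(aggregates[:, 1])
    return WeightAgeResult(
        table=table,
        complex_r=cx_r, complex_p=cx_p,
        basic_r=ba_r, basic_p=ba_p,
        excluded=excluded,
    )
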