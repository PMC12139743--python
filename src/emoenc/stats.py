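"""Inference on encoding-model prediction accuracies.

Group-level parametric tests (one-sample, paired, two-sample t) on
per-participant mean r values, the speech-minus-music voice-effect
contrast, and the non-parametric temporal-shuffle permutation test: the
feature timecourse is shuffled in time, the full design + blocked-CV
ridge analysis re-run, and the observed accuracy compared against the
null distribution of shuffled accuracies (two-tailed, with the +1
small-sample correction so p is never exactly 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data import BinnedHFB, FeatureTimecourses
from .design import DEFAULT_LAGS, build_lagged_design, concatenate_contacts
from .encoding import cv_evaluate
from .errors import DegenerateDataError

__all__ = [
    "TTestResult",
    "PermutationResult",
    "one_sample_t",
    "paired_t",
    "unpaired_t",
    "voice_effect",
    "shuffle_features_in_time",
    "permutation_test",
    "group_permutation_test",
    "group_for_age",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class PermutationResult:
    observed_r: float
    null_r: np.ndarray
    p_two_tailed: float

    def __post_init__(self) -> None:
        if not 0 < self.p_two_tailed <= 1:
            raise ValueError("permutation p must lie in (0, 1]")


def group_for_age(age: float) -> str:
    """Developmental group by age: < 13 years childhood, >= 13
    post-childhood.  Ages in (10, 13) fall outside both study ranges and
    are rejected."""
    if age < 5:
        raise ValueError(f"age {age} below the studied range")
    if 10 < age < 13:
        raise ValueError(f"age {age} lies between the study's group ranges")
    return "childhood" if age < 13 else "post_childhood"


def one_sample_t(values) -> TTestResult:
    """Two-sided one-sample t test of the mean against 0."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if v.std(ddof=1) == 0:
        raise DegenerateDataError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(v, 0.0)
    return TTestResult(float(res.statistic), int(v.size - 1), float(res.pvalue))


def paired_t(a, b) -> TTestResult:
    """Two-sided paired t test (t on the within-participant differences)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have matching lengths")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    if np.std(a - b, ddof=1) == 0:
        raise DegenerateDataError("zero-variance differences: t undefined")
    res = sps.ttest_rel(a, b)
    return TTestResult(float(res.statistic), int(a.size - 1), float(res.pvalue))


def unpaired_t(group_a, group_b) -> TTestResult:
    """Two-sided two-sample Student t test (equal-variance form)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, int(a.size + b.size - 2), 1.0)
        raise DegenerateDataError("zero pooled variance: t undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), int(a.size + b.size - 2),
                       float(res.pvalue))


def voice_effect(
    r_speech, r_music, groups=None
) -> tuple[np.ndarray, TTestResult | None]:
    """Per-participant speech-minus-music accuracy difference, plus the
    between-group contrast on those differences when two groups are
    given (labels aligned with the r vectors)."""
    rs = np.asarray(r_speech, float)
    rm = np.asarray(r_music, float)
    if rs.shape != rm.shape:
        raise ValueError("both conditions required per participant")
    d = rs - rm
    contrast = None
    if groups is not None:
        groups = np.asarray(groups)
        labels = sorted(set(groups.tolist()))
        if len(labels) != 2:
            raise ValueError("group contrast needs exactly two group labels")
        contrast = unpaired_t(d[groups == labels[0]], d[groups == labels[1]])
    return d, contrast


def shuffle_features_in_time(
    features: FeatureTimecourses, rng: np.random.Generator
) -> FeatureTimecourses:
    """Permute the 2 Hz time bins uniformly at random across all present
    blocks, jointly over the 48 features (cross-feature structure is
    preserved; each feature's marginal distribution is exactly
    preserved)."""
    blocks = features.block_indices
    mats = [features.blocks[b] for b in blocks]
    widths = [m.shape[1] for m in mats]
    cat = np.concatenate(mats, axis=1)
    perm = rng.permutation(cat.shape[1])
    cat = cat[:, perm]
    out: dict[int, np.ndarray] = {}
    start = 0
    for b, w in zip(blocks, widths):
        out[b] = cat[:, start : start + w]
        start += w
    return FeatureTimecourses(features.names, features.fs, out)


def _mean_r(
    features: FeatureTimecourses,
    binned: BinnedHFB,
    lags: tuple[float, ...],
    lam: float,
    k_folds: int,
) -> float:
    design = build_lagged_design(features, lags)
    X, y, blocks, _ = concatenate_contacts(binned, design)
    return cv_evaluate(X, y, blocks, lam, k_folds).mean_r


def permutation_test(
    features: FeatureTimecourses,
    binned_hfb: BinnedHFB,
    lam: float,
    lags: tuple[float, ...] = DEFAULT_LAGS,
    k_folds: int = 5,
    n_perm: int = 5000,
    seed: int = 0,
    mode: str = "shuffle",
) -> PermutationResult:
    """Temporal-shuffle permutation test on prediction accuracy.

    Each iteration shuffles the feature time bins (before lagging),
    re-runs the design construction and blocked ridge CV, and records
    the mean r.  Two-tailed p with the +1 correction:
    p = (#{|null| >= |observed|} + 1) / (n_perm + 1).

    ``mode='circular'`` replaces the uniform shuffle by independent
    circular shifts of each block's timecourse — a stricter null that
    preserves within-block autocorrelation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("shuffle", "circular"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    observed = _mean_r(features, binned_hfb, lags, lam, k_folds)
    null = np.empty(n_perm)
    for i in range(n_perm):
        if mode == "shuffle":
            perm_feats = shuffle_features_in_time(features, rng)
        else:
            shifted = {
                b: np.roll(m, int(rng.integers(m.shape[1])), axis=1)
                for b, m in features.blocks.items()
            }
            perm_feats = FeatureTimecourses(features.names, features.fs, shifted)
        null[i] = _mean_r(perm_feats, binned_hfb, lags, lam, k_folds)
    p = (np.sum(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1)
    return PermutationResult(observed_r=observed, null_r=null,
                             p_two_tailed=float(p))


def group_permutation_test(
    features: FeatureTimecourses,
    binned_list: list[BinnedHFB],
    lam: float,
    lags: tuple[float, ...] = DEFAULT_LAGS,
    k_folds: int = 5,
    n_perm: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Group-level temporal-shuffle test on the across-participant mean
    accuracy.

    Each iteration shuffles the shared feature timecourse independently
    per participant, re-runs the full analysis for every participant,
    and records the mean of their accuracies; the observed group mean is
    compared to that null (two-tailed, +1 correction).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not binned_list:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    observed = float(np.mean(
        [_mean_r(features, b, lags, lam, k_folds) for b in binned_list]
    ))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.mean([
            _mean_r(shuffle_features_in_time(features, rng), b, lags, lam,
                    k_folds)
            for b in binned_list
        ])
    p = (np.sum(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1)
    return PermutationResult(observed_r=observed, null_r=null,
                             p_two_tailed=float(p))
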