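"""Regression design construction.

Turns per-frame face tables into 2 Hz feature timecourses, builds the
time-lagged design matrix (lags 0, 0.5, 1 s by default), bins the HFB
response into 500 ms windows and concatenates contacts within an area so
a single weight vector is fitted per (participant, area, condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BinnedHFB, FeatureTimecourses, HFBEpochs
from .errors import SchemaError

__all__ = [
    "LaggedDesign",
    "DEFAULT_LAGS",
    "max_over_faces",
    "resample_to_2hz",
    "build_lagged_design",
    "bin_response",
    "concatenate_contacts",
]

DEFAULT_LAGS: tuple[float, ...] = (0.0, 0.5, 1.0)


@dataclass
class LaggedDesign:
    """Lagged feature design matrix.

    ``X`` is [n_timebins x (n_features * n_lags)]; columns are ordered
    lag-major: all features at the first lag, then all at the second,
    etc.  ``column_labels`` holds the (feature, lag) pair of each column
    and ``block_of_row`` the stimulus block of each row (rows exist only
    for blocks with features present).
    """

    X: np.ndarray
    lags: tuple[float, ...]
    column_labels: list[tuple[str, float]]
    block_of_row: np.ndarray

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.column_labels):
            raise ValueError("column_labels must match X columns")
        if self.X.shape[0] != len(self.block_of_row):
            raise ValueError("block_of_row must match X rows")
        if not np.isfinite(self.X).all():
            raise ValueError("design matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def max_over_faces(face_table: pd.DataFrame, feature_names) -> pd.DataFrame:
    """Per-frame feature scores as the maximum over detected faces.

    ``face_table`` has one row per (frame, face) with columns ``time_s``,
    ``face_id`` and one column per feature, scores in [0, 1].  Frames with
    no detected face (all feature columns NaN, or absent rows) score 0 on
    every feature: no face on screen means no facial emotion present.

    Returns a frame indexed by ``time_s`` with one row per frame.
    """
    names = list(feature_names)
    missing = [n for n in names if n not in face_table.columns]
    if missing:
        raise SchemaError(f"face table missing feature columns: {missing}")
    scores = face_table[names].to_numpy(float)
    finite = np.isfinite(scores)
    if np.any((scores[finite] < 0) | (scores[finite] > 1)):
        raise ValueError("face scores must lie in [0, 1]")
    out = face_table.groupby("time_s", sort=True)[names].max()
    return out.fillna(0.0)


def resample_to_2hz(
    frame_features: pd.DataFrame,
    block_dur: float,
    fs_out: float = 2.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Average per-frame features into the 0.5 s bins of one block.

    ``frame_features`` is indexed by frame time in seconds (block-relative
    after subtracting ``t0``); bins are half-open [t, t + 1/fs_out).
    Bin-averaging rather than interpolation is used so that irregular
    face-detection gaps do not leak values across bins; bins with no
    frame get 0.  Returns [n_features x n_bins].
    """
    if len(frame_features) == 0:
        raise ValueError("empty block: no frames to resample")
    t = frame_features.index.to_numpy(float) - t0
    if np.any(np.diff(t) < 0):
        raise ValueError("frame times must be increasing")
    n_bins = int(round(block_dur * fs_out))
    which = np.floor(t * fs_out).astype(int)
    ok = (which >= 0) & (which < n_bins)
    vals = frame_features.to_numpy(float)[ok]
    which = which[ok]
    n_feat = vals.shape[1]
    sums = np.zeros((n_bins, n_feat))
    counts = np.bincount(which, minlength=n_bins).astype(float)
    for j in range(n_feat):
        sums[:, j] = np.bincount(which, weights=vals[:, j], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        out = np.where(counts[:, None] > 0, sums / np.maximum(counts[:, None], 1), 0.0)
    return out.T


def build_lagged_design(
    features: FeatureTimecourses,
    lags: tuple[float, ...] = DEFAULT_LAGS,
) -> LaggedDesign:
    """Stack time-lagged copies of every feature into a design matrix.

    Lag l shifts the feature forward in time (the neural response follows
    the stimulus): column (f, l) at bin t holds x_f(t - l).  Lagged
    samples falling before a block's start are zero — blocks are separate
    epochs and are never lag-convolved across their boundaries.
    """
    step = 1.0 / features.fs
    lag_bins = []
    for lag in lags:
        nb = lag * features.fs
        if abs(nb - round(nb)) > 1e-9:
            raise ValueError(f"lag {lag} s is not a multiple of the {step} s grid")
        lag_bins.append(int(round(nb)))
    n_feat = features.n_features
    rows, block_of_row = [], []
    for b in features.block_indices:
        x = features.blocks[b]        # [n_feat x n_bins]
        n_bins = x.shape[1]
        cols = np.zeros((n_bins, n_feat * len(lags)))
        for k, nb in enumerate(lag_bins):
            sl = cols[:, k * n_feat : (k + 1) * n_feat]
            if nb == 0:
                sl[:] = x.T
            elif nb < n_bins:
                sl[nb:, :] = x[:, : n_bins - nb].T
        rows.append(cols)
        block_of_row.append(np.full(n_bins, b))
    if not rows:
        raise ValueError("no feature blocks to build a design from")
    labels = [(f, lag) for lag in lags for f in features.names]
    return LaggedDesign(
        X=np.vstack(rows),
        lags=tuple(lags),
        column_labels=labels,
        block_of_row=np.concatenate(block_of_row),
    )


def bin_response(epochs: HFBEpochs, bin_dur: float = 0.5) -> BinnedHFB:
    """Average HFB epochs into 500 ms bins (60 bins per 30 s block at
    the 2 Hz grid of the features)."""
    per_bin = epochs.fs * bin_dur
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("bin duration must hold an integer number of samples")
    per_bin = int(round(per_bin))
    n_ch, n_blocks, n_samp = epochs.amplitude.shape
    if n_samp % per_bin:
        raise ValueError(
            f"epoch length {n_samp} not divisible into {per_bin}-sample bins"
        )
    n_bins = n_samp // per_bin
    binned = epochs.amplitude.reshape(n_ch, n_blocks, n_bins, per_bin).mean(axis=3)
    return BinnedHFB(binned, list(epochs.schedule.block_index), fs=1.0 / bin_dur)


def concatenate_contacts(
    binned: BinnedHFB, design: LaggedDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack all contacts of an area over a shared design.

    The response vectors of the contacts are concatenated vertically and
    the design matrix replicated once per contact, so one weight vector
    is fitted jointly to every contact of the area.  Only blocks present
    in the design (features available) contribute rows.

    Returns ``(X_stacked, y, block_of_row, contact_of_row)``.
    """
    if binned.n_contacts < 1:
        raise ValueError("need at least one contact")
    design_blocks = sorted(set(int(b) for b in design.block_of_row))
    sub = binned.subset(design_blocks)
    y_one = []
    for b in design_blocks:
        pos = sub.block_indices.index(b)
        y_one.append(sub.values[:, pos, :])
    # [n_contacts x n_rows] in design row order
    y_by_contact = np.concatenate(y_one, axis=1)
    if y_by_contact.shape[1] != design.n_rows:
        raise ValueError(
            f"response rows ({y_by_contact.shape[1]}) do not match design rows "
            f"({design.n_rows})"
        )
    n_c = binned.n_contacts
    X = np.tile(design.X, (n_c, 1))
    y = y_by_contact.reshape(-1)
    blocks = np.tile(design.block_of_row, n_c)
    contacts = np.repeat(np.arange(n_c), design.n_rows)
    return X, y, blocks, contacts
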