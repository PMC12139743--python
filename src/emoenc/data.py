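"""In-memory containers shared across the pipeline.

Time convention: seconds, onsets relative to recording start; 2 Hz bins
are labelled by their left edge and cover the half-open interval
[t, t + 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BlockSchedule",
    "FeatureTimecourses",
    "BinnedHFB",
    "RecordingSession",
    "HFBEpochs",
]


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered stimulus blocks: onsets/durations in seconds, condition
    ('speech' or 'music') and a per-block features-present flag (the
    movie's fifth music block shows no faces and is excluded from the
    feature analysis)."""

    onset: np.ndarray          # [n_blocks], s
    duration: np.ndarray       # [n_blocks], s
    condition: tuple[str, ...]
    block_index: np.ndarray    # [n_blocks], 0-based
    features_present: np.ndarray  # [n_blocks], bool

    def __post_init__(self) -> None:
        n = len(self.onset)
        for name in ("duration", "block_index", "features_present"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"schedule field {name!r} length mismatch")
        if len(self.condition) != n:
            raise ValueError("schedule condition length mismatch")
        if np.any(np.diff(self.onset) <= 0):
            raise ValueError("block onsets must be strictly increasing")
        offsets = self.onset + self.duration
        if np.any(self.onset[1:] < offsets[:-1]):
            raise ValueError("blocks must not overlap")
        bad = set(self.condition) - {"speech", "music"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    @property
    def n_blocks(self) -> int:
        return len(self.onset)

    def blocks_for(self, condition: str, present_only: bool = True) -> np.ndarray:
        """Block indices of one condition (by default only those with
        facial features present)."""
        mask = np.array([c == condition for c in self.condition])
        if present_only:
            mask &= self.features_present
        return self.block_index[mask]

    @property
    def present_blocks(self) -> np.ndarray:
        return self.block_index[self.features_present]

    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type, ...)."""
        return pd.DataFrame(
            {
                "onset": self.onset,
                "duration": self.duration,
                "trial_type": list(self.condition),
                "block_index": self.block_index,
                "features_present": self.features_present.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BlockSchedule":
        return cls(
            onset=df["onset"].to_numpy(float),
            duration=df["duration"].to_numpy(float),
            condition=tuple(df["trial_type"].astype(str)),
            block_index=df["block_index"].to_numpy(int),
            features_present=df["features_present"].to_numpy().astype(bool),
        )


@dataclass
class FeatureTimecourses:
    """Per-block facial-emotion feature matrices on the 2 Hz grid.

    ``blocks[b]`` is a [n_features x n_bins] array of scores in [0, 1]
    for stimulus block ``b``; blocks without facial features simply have
    no entry.
    """

    names: tuple[str, ...]
    fs: float                      # Hz, 2.0 in the standard analysis
    blocks: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for b, arr in self.blocks.items():
            if arr.ndim != 2 or arr.shape[0] != len(self.names):
                raise ValueError(
                    f"block {b}: expected [{len(self.names)} x n_bins] array, "
                    f"got {arr.shape}"
                )
            if not np.isfinite(arr).all():
                raise ValueError(f"block {b}: non-finite feature values")

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def block_indices(self) -> list[int]:
        return sorted(self.blocks)

    def subset(self, block_indices) -> "FeatureTimecourses":
        keep = {int(b): self.blocks[int(b)] for b in block_indices if int(b) in self.blocks}
        return FeatureTimecourses(self.names, self.fs, keep)

    def n_bins(self, block: int) -> int:
        return self.blocks[block].shape[1]


@dataclass
class BinnedHFB:
    """HFB response binned on the 2 Hz grid, per contact and block.

    ``values`` is [n_contacts x n_blocks x n_bins] in baseline z-units;
    ``block_indices`` names the stimulus block of each middle axis slot.
    """

    values: np.ndarray
    block_indices: list[int]
    fs: float = 2.0

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("BinnedHFB values must be [contacts x blocks x bins]")
        if self.values.shape[1] != len(self.block_indices):
            raise ValueError("block_indices length must match values axis 1")

    @property
    def n_contacts(self) -> int:
        return self.values.shape[0]

    def subset(self, block_indices) -> "BinnedHFB":
        wanted = [int(b) for b in block_indices]
        pos = [self.block_indices.index(b) for b in wanted]
        return BinnedHFB(self.values[:, pos, :], wanted, self.fs)


@dataclass
class RecordingSession:
    """Raw (or amplitude-transformed) multichannel recording."""

    signal: np.ndarray                 # [n_channels x n_samples], microvolts
    fs: float                          # Hz
    channel_names: list[str]
    channel_regions: list[str]         # 'DLPFC' | 'pSTC' | 'other'
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.ndim != 2:
            raise ValueError("signal must be [n_channels x n_samples]")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")
        if len(self.channel_regions) != self.signal.shape[0]:
            raise ValueError("channel_regions length must match signal rows")
        good = self.good_mask
        if good.any() and not np.isfinite(self.signal[good]).all():
            raise ValueError("non-finite samples in good channels")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def good_mask(self) -> np.ndarray:
        return np.array([c not in self.bad_channels for c in self.channel_names])

    def copy_with(self, signal: np.ndarray) -> "RecordingSession":
        return RecordingSession(
            signal=signal,
            fs=self.fs,
            channel_names=list(self.channel_names),
            channel_regions=list(self.channel_regions),
            bad_channels=set(self.bad_channels),
        )


@dataclass
class HFBEpochs:
    """Baseline-z-scored HFB amplitude epochs.

    ``amplitude`` is [n_channels x n_blocks x n_samples] at ``fs``
    (400 Hz in the standard chain), spanning [0, block duration); each
    contact/block was z-scored against its own -0.2-0 s baseline.
    """

    amplitude: np.ndarray
    fs: float
    schedule: BlockSchedule
    channel_names: list[str]
    channel_regions: list[str]

    def __post_init__(self) -> None:
        if self.amplitude.ndim != 3:
            raise ValueError("amplitude must be [channels x blocks x samples]")
        if self.amplitude.shape[1] != self.schedule.n_blocks:
            raise ValueError("epoch count must match schedule")

    @property
    def n_channels(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_samples_per_block(self) -> int:
        return self.amplitude.shape[2]
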