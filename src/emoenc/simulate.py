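"""Synthetic movie-watching cohorts with known encoding ground truth.

Every downstream stage (preprocessing, design, ridge fitting, inference,
weight analysis) is testable without patient data: this module emulates
the study's structure — 13 interleaved 30 s speech/music blocks, a
feature-absent fifth music block, 48 bounded facial-emotion feature
timecourses on a 2 Hz grid — and generates per-contact HFB responses
from known lagged weights plus noise.  A cohort generator adds the
age-structured effects of interest: a complex-emotion weight gradient
with age, and a built-in null (zero weights) for childhood DLPFC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .data import BinnedHFB, BlockSchedule, FeatureTimecourses, RecordingSession
from .design import DEFAULT_LAGS, build_lagged_design
from .features import EmotionFeatureSet, default_feature_set

__all__ = [
    "GroundTruth",
    "ParticipantSpec",
    "CohortSpec",
    "Cohort",
    "ParticipantData",
    "generate_block_schedule",
    "generate_feature_timecourses",
    "generate_face_table",
    "synthesize_binned_hfb",
    "synthesize_raw_signal",
    "generate_cohort",
    "default_cohort_spec",
    "sample_ground_truth_weights",
]

AREAS = ("DLPFC", "pSTC")


@dataclass(frozen=True)
class GroundTruth:
    """True lagged encoding weights and the noise level of the
    synthetic binned HFB response.

    ``weights`` is [n_features x n_lags] (unitless); ``noise_sd`` is the
    SD of the additive Gaussian noise on the 2 Hz binned response, in
    z-units.
    """

    weights: np.ndarray
    noise_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights).all():
            raise ValueError("ground-truth weights must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def sample_ground_truth_weights(
    rng: np.random.Generator,
    n_features: int = 48,
    n_lags: int = 3,
    density: float = 1 / 6,
    scale: float = 0.3,
) -> np.ndarray:
    """Sparse, heavy-tailed true encoding weights.

    A cortical site encodes a minority of the facial-emotion features
    (on average ``density`` of them) with exponentially distributed
    effect scales and random signs across lags — the selectivity
    structure typical of encoding-model studies.  Guaranteed at least
    one encoded feature.  Returns [n_features x n_lags].
    """
    mask = rng.random(n_features) < density
    if not mask.any():
        mask[rng.integers(n_features)] = True
    per_feat = np.where(mask, rng.exponential(scale, n_features), 0.0)
    return per_feat[:, None] * rng.standard_normal((n_features, n_lags))


@dataclass(frozen=True)
class ParticipantSpec:
    id: str
    age: float                      # years
    group: str                      # 'childhood' | 'post_childhood'
    areas: dict[str, int] = field(default_factory=dict)  # area -> contact count
    sex: str | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout plus the age-structured effect to build in.

    ``complex_age_slope`` is the true weight increase per year of age
    applied to every complex-emotion feature (all lags); ``voice_gain``
    scales the true weights during music blocks (1.0 = no voice effect,
    < 1 emulates reduced encoding when speech is absent).
    """

    participants: tuple[ParticipantSpec, ...]
    complex_age_slope: float = 0.0
    voice_gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.participants:
            raise ValueError("cohort must contain at least one participant")
        for p in self.participants:
            if p.group == "childhood" and not (5 <= p.age <= 10):
                raise ValueError(f"{p.id}: childhood ages must lie in [5, 10]")
            if p.group == "post_childhood" and not (13 <= p.age <= 55):
                raise ValueError(f"{p.id}: post-childhood ages must lie in [13, 55]")
            if p.group not in ("childhood", "post_childhood"):
                raise ValueError(f"{p.id}: unknown group {p.group!r}")
            for area, n in p.areas.items():
                if area not in AREAS:
                    raise ValueError(f"{p.id}: unknown area {area!r}")
                if n < 4:
                    raise ValueError(
                        f"{p.id}: at least four contacts per covered area required"
                    )

    @property
    def min_age(self) -> float:
        return min(p.age for p in self.participants)


def generate_block_schedule(
    n_blocks: int,
    block_dur: float,
    seed: int = 0,
    gap: float = 2.0,
    start_offset: float = 2.0,
    movie_layout: bool = True,
) -> BlockSchedule:
    """Alternating speech/music block schedule.

    With an odd block count the sequence starts with music so that music
    blocks are in the majority (the movie has 7 music + 6 speech blocks);
    with an even count the starting condition is drawn from ``seed``.
    When ``movie_layout`` is set and there are at least 13 blocks, the
    fifth music block is flagged feature-absent (no faces on screen).
    Gaps between blocks leave room for the -0.2-0 s baseline window.
    """
    if n_blocks < 2:
        raise ValueError("need at least two blocks")
    if block_dur <= 0:
        raise ValueError("block duration must be positive")
    if gap < 0.2 or start_offset < 0.2:
        raise ValueError("gaps must cover the 0.2 s baseline window")
    rng = np.random.default_rng(seed)
    if n_blocks % 2 == 1:
        first = "music"
    else:
        first = str(rng.choice(["speech", "music"]))
    other = "speech" if first == "music" else "music"
    condition = tuple(first if i % 2 == 0 else other for i in range(n_blocks))
    onset = start_offset + np.arange(n_blocks) * (block_dur + gap)
    features_present = np.ones(n_blocks, bool)
    if movie_layout and n_blocks >= 13:
        music_positions = [i for i, c in enumerate(condition) if c == "music"]
        features_present[music_positions[4]] = False
    return BlockSchedule(
        onset=onset,
        duration=np.full(n_blocks, float(block_dur)),
        condition=condition,
        block_index=np.arange(n_blocks),
        features_present=features_present,
    )


def generate_feature_timecourses(
    schedule: BlockSchedule,
    fs_feat: float = 2.0,
    smoothness: float = 2.0,
    seed: int = 0,
    feature_set: EmotionFeatureSet | None = None,
) -> FeatureTimecourses:
    """Bounded, temporally smooth feature timecourses per present block.

    Each feature is a Gaussian process emulated by smoothing white noise
    with a Gaussian kernel of SD ``smoothness`` seconds, standardised and
    affinely mapped into [0, 1] with clipping.  Only smoothness and
    boundedness matter downstream; feature-absent blocks yield nothing.
    """
    if fs_feat <= 0:
        raise ValueError("feature sampling rate must be positive")
    fset = feature_set or default_feature_set()
    rng = np.random.default_rng(seed)
    blocks: dict[int, np.ndarray] = {}
    for i in range(schedule.n_blocks):
        if not schedule.features_present[i]:
            continue
        n_bins = int(round(schedule.duration[i] * fs_feat))
        z = rng.standard_normal((fset.n_features, n_bins))
        sigma = smoothness * fs_feat
        if sigma > 0:
            z = gaussian_filter1d(z, sigma, axis=1, mode="reflect")
        sd = z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=1, keepdims=True)) / sd
        blocks[int(schedule.block_index[i])] = np.clip(0.5 + 0.25 * z, 0.0, 1.0)
    return FeatureTimecourses(names=fset.names, fs=fs_feat, blocks=blocks)


def generate_face_table(
    features: FeatureTimecourses,
    block: int,
    block_onset: float = 0.0,
    fps: float = 25.0,
    max_faces: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-frame, per-face score table whose max-over-faces tracks one
    block's feature timecourse (for exercising the face-table ingest
    path).  Frame times are absolute (block onset + frame offset); extra
    faces get scores dominated by the first face."""
    rng = np.random.default_rng(seed)
    x = features.blocks[block]                      # [n_feat x n_bins]
    n_bins = x.shape[1]
    t_frames = np.arange(0, n_bins / features.fs, 1.0 / fps)
    bin_of_frame = np.minimum((t_frames * features.fs).astype(int), n_bins - 1)
    rows = []
    for t, b in zip(t_frames, bin_of_frame):
        n_faces = rng.integers(1, max_faces + 1)
        lead = rng.integers(0, n_faces)
        for f in range(n_faces):
            scores = x[:, b] if f == lead else x[:, b] * rng.uniform(0, 1)
            rows.append(
                {"time_s": block_onset + t, "face_id": f,
                 **dict(zip(features.names, scores))}
            )
    return pd.DataFrame(rows)


def synthesize_binned_hfb(
    features: FeatureTimecourses,
    truth: GroundTruth,
    lags: tuple[float, ...] = DEFAULT_LAGS,
    n_contacts: int = 1,
    rng: np.random.Generator | None = None,
) -> BinnedHFB:
    """Forward model: binned HFB from features and true lagged weights.

    y(t) = sum_f sum_l w[f, l] x_f(t - lag_l) + eps,  eps ~ N(0, noise_sd^2),
    on the 2 Hz grid, with lagged samples outside a block treated as 0.
    All contacts of the output share the weights; noise is independent
    per contact.
    """
    n_feat, n_lags = truth.weights.shape
    if n_feat != features.n_features:
        raise ValueError(
            f"weights rows ({n_feat}) must match feature count "
            f"({features.n_features})"
        )
    if n_lags != len(lags):
        raise ValueError(f"weights columns ({n_lags}) must match lags ({len(lags)})")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    design = build_lagged_design(features, lags)
    # column order is lag-major: weights.T ravels to match
    w_flat = truth.weights.T.reshape(-1)
    y_clean = design.X @ w_flat
    blocks = features.block_indices
    n_bins = {b: features.n_bins(b) for b in blocks}
    if len(set(n_bins.values())) != 1:
        raise ValueError("blocks must share a common bin count")
    nb = next(iter(n_bins.values()))
    clean = y_clean.reshape(len(blocks), nb)
    values = clean[None, :, :] + truth.noise_sd * rng.standard_normal(
        (n_contacts, len(blocks), nb)
    )
    return BinnedHFB(values=values, block_indices=list(blocks), fs=features.fs)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def synthesize_raw_signal(
    binned_hfb: BinnedHFB,
    schedule: BlockSchedule,
    fs_raw: float = 1000.0,
    carrier_band: tuple[float, float] = (110.0, 140.0),
    seed: int = 0,
    base_level: float = 1.0,
    gain: float = 0.5,
    line_amp: float = 0.05,
    pink_sd: float = 0.05,
    regions: list[str] | None = None,
) -> RecordingSession:
    """Raw carrier traces whose HFB envelope encodes a target series.

    Each contact's trace is carrier-band noise (envelope-normalised so
    its analytic amplitude is flat) amplitude-modulated by the upsampled
    target envelope, squared to invert the preprocessing chain's
    square-root transform, plus a 50 Hz line component and broadband
    pink noise.  Outside blocks (including the pre-block baseline) the
    envelope sits at ``base_level``.  Running the standard preprocessing
    chain on the output recovers a signal correlating with the target.
    """
    from scipy.signal import butter, hilbert, sosfiltfilt

    lo, hi = carrier_band
    if fs_raw < 2 * hi:
        raise ValueError(
            f"fs_raw={fs_raw} violates Nyquist for carrier band up to {hi} Hz"
        )
    rng = np.random.default_rng(seed)
    n_contacts = binned_hfb.n_contacts
    duration = float(schedule.onset[-1] + schedule.duration[-1] + 2.0)
    n = int(round(duration * fs_raw))
    t = np.arange(n) / fs_raw

    # sqrt-amplitude envelope per contact: baseline level plus the target
    env = np.full((n_contacts, n), base_level)
    bin_step = 1.0 / binned_hfb.fs
    for pos, b in enumerate(binned_hfb.block_indices):
        i = int(np.where(schedule.block_index == b)[0][0])
        onset, dur = schedule.onset[i], schedule.duration[i]
        centers = onset + (np.arange(binned_hfb.values.shape[2]) + 0.5) * bin_step
        in_block = (t >= onset) & (t < onset + dur)
        for c in range(n_contacts):
            env[c, in_block] = base_level + gain * np.interp(
                t[in_block], centers, binned_hfb.values[c, pos, :]
            )
    env = gaussian_filter1d(env, 0.05 * fs_raw, axis=1)
    env = np.maximum(env, 0.05)

    sos = butter(4, [lo, hi], btype="bandpass", fs=fs_raw, output="sos")
    sig = np.empty((n_contacts, n))
    phase = rng.uniform(0, 2 * np.pi, n_contacts)
    for c in range(n_contacts):
        bp = sosfiltfilt(sos, rng.standard_normal(n))
        own_env = gaussian_filter1d(np.abs(hilbert(bp)), 0.025 * fs_raw)
        carrier = bp / np.maximum(own_env, 1e-12)
        sig[c] = (
            env[c] ** 2 * carrier
            + line_amp * np.sin(2 * np.pi * 50.0 * t + phase[c])
            + pink_sd * _pink_noise(rng, n)
        )
    names = [f"ch{c:02d}" for c in range(n_contacts)]
    return RecordingSession(
        signal=sig,
        fs=fs_raw,
        channel_names=names,
        channel_regions=regions or ["other"] * n_contacts,
    )


@dataclass
class ParticipantData:
    """One synthetic participant: binned HFB per covered area plus the
    true weights each area's response was generated from."""

    id: str
    age: float
    group: str
    sex: str | None
    binned: dict[str, BinnedHFB]
    true_weights: dict[str, np.ndarray]   # area -> [n_features x n_lags]


@dataclass
class Cohort:
    schedule: BlockSchedule
    features: FeatureTimecourses
    feature_set: EmotionFeatureSet
    lags: tuple[float, ...]
    participants: list[ParticipantData]

    def metadata(self) -> pd.DataFrame:
        """Participant table (id, sex, age, group, contacts per area)."""
        rows = []
        for p in self.participants:
            rows.append(
                {
                    "participant_id": p.id,
                    "sex": p.sex if p.sex is not None else "n/a",
                    "age": p.age,
                    "group": p.group,
                    "n_contacts_DLPFC": p.binned["DLPFC"].n_contacts
                    if "DLPFC" in p.binned else 0,
                    "n_contacts_pSTC": p.binned["pSTC"].n_contacts
                    if "pSTC" in p.binned else 0,
                }
            )
        return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec,
    base_truth: GroundTruth,
    seed: int = 0,
    feature_set: EmotionFeatureSet | None = None,
    lags: tuple[float, ...] = DEFAULT_LAGS,
    n_blocks: int = 13,
    block_dur: float = 30.0,
) -> Cohort:
    """Whole synthetic cohort watching one shared movie.

    All participants share the schedule and feature timecourses (one
    stimulus).  Per participant and area, true weights are the base
    weights with ``complex_age_slope * (age - min age)`` added to every
    complex-emotion feature at every lag; childhood DLPFC weights are
    zeroed (facial emotion not encoded in children's DLPFC — a built-in
    null with known truth).  Music-block responses use the weights
    scaled by ``voice_gain``.
    """
    fset = feature_set or default_feature_set()
    if base_truth.weights.shape != (fset.n_features, len(lags)):
        raise ValueError("base weights must be [n_features x n_lags]")
    ss = np.random.SeedSequence(seed)
    sched_seed, feat_seed, *p_seeds = [
        s.generate_state(1)[0] % (2**31) for s in ss.spawn(2 + len(spec.participants))
    ]
    schedule = generate_block_schedule(n_blocks, block_dur, seed=int(sched_seed))
    features = generate_feature_timecourses(schedule, seed=int(feat_seed),
                                            feature_set=fset)
    cx_rows = fset.indices(fset.complex_set)
    min_age = spec.min_age
    participants = []
    for p, pseed in zip(spec.participants, p_seeds):
        rng = np.random.default_rng(int(pseed))
        binned: dict[str, BinnedHFB] = {}
        truths: dict[str, np.ndarray] = {}
        for area, n_contacts in sorted(p.areas.items()):
            w = base_truth.weights.copy()
            w[cx_rows, :] += spec.complex_age_slope * (p.age - min_age)
            if p.group == "childhood" and area == "DLPFC":
                w = np.zeros_like(w)
            truths[area] = w
            parts = []
            order: list[int] = []
            for cond in ("speech", "music"):
                blocks = schedule.blocks_for(cond)
                blocks = [b for b in blocks if b in features.blocks]
                if not blocks:
                    continue
                w_cond = w if cond == "speech" else w * spec.voice_gain
                tc = GroundTruth(w_cond, base_truth.noise_sd, base_truth.seed)
                parts.append(
                    synthesize_binned_hfb(
                        features.subset(blocks), tc, lags,
                        n_contacts=n_contacts, rng=rng,
                    )
                )
                order.extend(int(b) for b in blocks)
            values = np.concatenate([b.values for b in parts], axis=1)
            # restore ascending block order
            perm = np.argsort(order)
            binned[area] = BinnedHFB(
                values[:, perm, :], [order[i] for i in perm], fs=features.fs
            )
        participants.append(
            ParticipantData(
                id=p.id, age=p.age, group=p.group, sex=p.sex,
                binned=binned, true_weights=truths,
            )
        )
    return Cohort(
        schedule=schedule, features=features, feature_set=fset,
        lags=tuple(lags), participants=participants,
    )


def default_cohort_spec(
    seed: int = 0,
    complex_age_slope: float = 0.0,
    voice_gain: float = 1.0,
) -> CohortSpec:
    """Cohort mirroring the study layout: 11 children (5-10 y, 8 with
    DLPFC and 4 with pSTC coverage) and 31 post-childhood individuals
    (13-55 y, 13 with DLPFC and 25 with pSTC), at least four contacts
    per covered area."""
    rng = np.random.default_rng(seed)
    participants: list[ParticipantSpec] = []

    child_ages = np.round(np.linspace(5, 10, 11) + rng.uniform(-0.3, 0.3, 11), 1)
    child_ages = np.clip(child_ages, 5, 10)
    child_sex = ["F"] * 7 + ["M"] * 4
    rng.shuffle(child_sex)
    for i in range(11):
        areas: dict[str, int] = {}
        if i < 8:
            areas["DLPFC"] = int(rng.integers(4, 9))
        if i >= 7:
            areas["pSTC"] = int(rng.integers(4, 9))
        participants.append(
            ParticipantSpec(
                id=f"C{i + 1:02d}", age=float(child_ages[i]),
                group="childhood", areas=areas, sex=child_sex[i],
            )
        )

    adult_ages = np.round(np.linspace(13, 55, 31) + rng.uniform(-0.4, 0.4, 31), 1)
    adult_ages = np.clip(adult_ages, 13, 55)
    adult_sex = ["F"] * 18 + ["M"] * 13
    rng.shuffle(adult_sex)
    for i in range(31):
        areas = {}
        if i < 13:
            areas["DLPFC"] = int(rng.integers(4, 9))
        if i >= 6:
            areas["pSTC"] = int(rng.integers(4, 9))
        participants.append(
            ParticipantSpec(
                id=f"P{i + 1:02d}", age=float(adult_ages[i]),
                group="post_childhood", areas=areas, sex=adult_sex[i],
            )
        )
    return CohortSpec(
        participants=tuple(participants),
        complex_age_slope=complex_age_slope,
        voice_gain=voice_gain,
    )
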