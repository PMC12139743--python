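"""Raw recording -> baseline-z-scored HFB amplitude epochs.

Fixed chain: 50 Hz notch -> common average reference -> 110-140 Hz
band-pass (4th-order Butterworth) + Hilbert analytic amplitude ->
per-block epoching ([-0.2, 30] s) -> downsample to 400 Hz -> square
root -> z-score against the block's own -0.2-0 s baseline.

All filtering is zero-phase (forward-backward), so envelope latencies
are not shifted; baseline statistics are computed after downsampling and
the square-root transform, i.e. the baseline undergoes exactly the same
transforms as the epoch it normalises.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.signal import butter, filtfilt, hilbert, iirnotch, resample_poly, sosfiltfilt

from .data import BlockSchedule, HFBEpochs, RecordingSession
from .errors import DegenerateDataError

__all__ = [
    "notch_50",
    "common_average_reference",
    "extract_hfb_amplitude",
    "epoch_and_normalize",
    "preprocess_session",
]

BASELINE_WINDOW = 0.2   # s before block onset
TARGET_FS = 400.0       # Hz after downsampling


def notch_50(session: RecordingSession, freq: float = 50.0, q: float = 30.0) -> RecordingSession:
    """Zero-phase narrow IIR notch at the 50 Hz line frequency.

    Only the fundamental is removed; harmonics sit outside both the
    analysis band and the 110-140 Hz carrier band.
    """
    if session.fs <= 2 * freq:
        raise ValueError(f"fs={session.fs} too low to notch {freq} Hz")
    b, a = iirnotch(freq, q, fs=session.fs)
    return session.copy_with(filtfilt(b, a, session.signal, axis=1))


def common_average_reference(session: RecordingSession) -> RecordingSession:
    """Subtract, at every sample, the mean over good channels.

    Bad channels are excluded from the average but still re-referenced
    by it.
    """
    good = session.good_mask
    if good.sum() < 2:
        raise ValueError("common average reference requires >= 2 good channels")
    car = session.signal[good].mean(axis=0, keepdims=True)
    return session.copy_with(session.signal - car)


def extract_hfb_amplitude(
    session: RecordingSession, band: tuple[float, float] = (110.0, 140.0)
) -> RecordingSession:
    """High-frequency broadband analytic amplitude per channel: 4th-order
    Butterworth band-pass (zero-phase) then the magnitude of the Hilbert
    analytic signal."""
    lo, hi = band
    if session.fs <= 2 * hi:
        raise ValueError(f"fs={session.fs} violates Nyquist for band up to {hi} Hz")
    sos = butter(4, [lo, hi], btype="bandpass", fs=session.fs, output="sos")
    bp = sosfiltfilt(sos, session.signal, axis=1)
    return session.copy_with(np.abs(hilbert(bp, axis=1)))


def epoch_and_normalize(
    session: RecordingSession,
    schedule: BlockSchedule,
    target_fs: float = TARGET_FS,
    baseline: float = BASELINE_WINDOW,
) -> HFBEpochs:
    """Cut blocks, downsample, square-root, baseline-z-score.

    Each block is cut over [onset - baseline, onset + duration], resampled
    to ``target_fs`` by a polyphase anti-aliased method, square-root
    transformed, and z-scored per contact against the mean/SD of its own
    pre-onset baseline samples.  The returned epochs span [0, duration).
    """
    frac = Fraction(target_fs / session.fs).limit_denominator(1000)
    durs = set(np.round(schedule.duration, 9))
    if len(durs) != 1:
        raise ValueError("blocks must share one duration to epoch jointly")
    dur = float(durs.pop())
    n_base = int(round(baseline * target_fs))
    n_keep = int(round(dur * target_fs))
    epochs = np.empty((session.n_channels, schedule.n_blocks, n_keep))
    for i in range(schedule.n_blocks):
        onset = schedule.onset[i]
        i0 = int(round((onset - baseline) * session.fs))
        i1 = int(round((onset + dur) * session.fs))
        if i0 < 0 or i1 > session.n_samples:
            raise ValueError(
                f"block {i} ([{onset - baseline}, {onset + dur}] s) exceeds the "
                "recording"
            )
        seg = session.signal[:, i0:i1]
        # linear-extension padding keeps the resampler's startup
        # transient out of the 0.2 s baseline window
        res = resample_poly(seg, frac.numerator, frac.denominator, axis=1,
                            padtype="line")
        # amplitude is non-negative; clip resampling ringing before sqrt
        res = np.sqrt(np.maximum(res, 0.0))
        if res.shape[1] < n_base + n_keep:
            raise ValueError("resampled epoch shorter than expected")
        base = res[:, :n_base]
        mu = base.mean(axis=1, keepdims=True)
        sd = base.std(axis=1, ddof=1, keepdims=True)
        # a baseline varying by less than 1e-4 of its mean is constant up
        # to resampler ripple; z-scoring against it would only amplify
        # that ripple
        if np.any(sd <= 1e-4 * np.maximum(np.abs(mu), 1.0)):
            raise DegenerateDataError(
                f"block {i}: zero-variance baseline on some contact"
            )
        epochs[:, i, :] = (res[:, n_base : n_base + n_keep] - mu) / sd
    return HFBEpochs(
        amplitude=epochs,
        fs=target_fs,
        schedule=schedule,
        channel_names=list(session.channel_names),
        channel_regions=list(session.channel_regions),
    )


def preprocess_session(
    session: RecordingSession,
    schedule: BlockSchedule,
    band: tuple[float, float] = (110.0, 140.0),
    notch: float = 50.0,
    target_fs: float = TARGET_FS,
    apply_car: bool = True,
) -> HFBEpochs:
    """Full fixed-order chain on a raw session.

    ``apply_car`` exists for single-channel diagnostics only; the
    standard analysis always re-references.
    """
    out = notch_50(session, freq=notch)
    if apply_car:
        out = common_average_reference(out)
    out = extract_hfb_amplitude(out, band=band)
    return epoch_and_normalize(out, schedule, target_fs=target_fs)
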