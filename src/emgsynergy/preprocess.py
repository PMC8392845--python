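"""Raw-signal conditioning and angle-driven motion segmentation.

The processing chain mirrors standard surface-EMG practice: band-pass
filtering (20-450 Hz, 4th-order Butterworth, applied zero-phase), mean
removal and full-wave rectification, per-channel normalization to the
session maximum, and a 100 ms moving-RMS envelope.  Motion repetitions are
delimited on the smoothed knee-angle trace: bell-shaped flexion/extension
excursions for the standing/sitting tasks, angle minima after each maximum
for gait cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateChannelError, DegenerateSegmentError, SamplingRateError

logger = logging.getLogger(__name__)

BANDPASS_LOW_HZ = 20.0
BANDPASS_HIGH_HZ = 450.0
FILTER_ORDER = 4
ENVELOPE_WINDOW_MS = 100.0
ANGLE_SMOOTH_MS = 100.0
SPEED_THRESHOLD_FRAC = 0.10
RESAMPLE_POINTS = 100


@dataclass
class EnvelopeMatrix:
    """Normalized non-negative sEMG envelopes, one row per channel.

    Entries lie in [0, 1]; a channel attains 1 at the sample where the
    subject's session-wide maximum occurred.
    """

    values: np.ndarray  # (m, n), entries in [0, 1]
    fs_effective: float


@dataclass
class MotionSegment:
    """One motion repetition: half-open sample range [start, end)."""

    start: int
    end: int
    motion: str
    envelope_resampled: np.ndarray | None = None  # (m, 100) once attached

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DegenerateSegmentError(
                f"segment end {self.end} must exceed start {self.start}"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def filter_and_rectify(
    raw: np.ndarray,
    fs: float,
    *,
    low_hz: float = BANDPASS_LOW_HZ,
    high_hz: float = BANDPASS_HIGH_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Band-pass, zero-center and full-wave rectify one raw sEMG trace.

    The Butterworth band-pass is applied forward-backward (zero phase) so
    the envelope stays time-aligned with the angle channel.  Returns
    ``|bandpass(raw) - mean(bandpass(raw))|``.
    """
    raw = np.asarray(raw, dtype=float)
    if fs <= 2 * high_hz:
        raise SamplingRateError(
            f"fs={fs} Hz too low for a {high_hz} Hz passband edge (need fs > {2 * high_hz})"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, raw)
    return np.abs(filtered - filtered.mean())


def moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving RMS with shrink-to-valid windows at the edges."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x**2, axis=-1)], axis=-1
    )
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    sums = csum[..., hi] - csum[..., lo]
    return np.sqrt(sums / (hi - lo))


def session_maxima(rectified_all: list[np.ndarray]) -> np.ndarray:
    """Per-channel maxima across all of a subject's rectified recordings."""
    stacked = [np.asarray(r, dtype=float) for r in rectified_all]
    m = stacked[0].shape[0]
    maxima = np.zeros(m)
    for r in stacked:
        maxima = np.maximum(maxima, r.max(axis=1))
    return maxima


def normalize_and_envelope(
    rectified: np.ndarray,
    fs: float,
    *,
    window_ms: float = ENVELOPE_WINDOW_MS,
    session_max: np.ndarray | None = None,
) -> EnvelopeMatrix:
    """Normalize each channel to its session maximum, then moving-RMS smooth.

    Parameters
    ----------
    rectified : ndarray, shape (m, T)
        Rectified sEMG, one row per channel.
    session_max : ndarray, shape (m,), optional
        Per-channel maxima over the subject's entire session (all motions).
        Defaults to this recording's own maxima.

    Raises
    ------
    DegenerateChannelError
        If a session maximum is zero or negative (flat channel).
    """
    rectified = np.atleast_2d(np.asarray(rectified, dtype=float))
    if session_max is None:
        session_max = rectified.max(axis=1)
    session_max = np.asarray(session_max, dtype=float)
    bad = np.flatnonzero(session_max <= 0)
    if bad.size:
        raise DegenerateChannelError(
            f"channel(s) {bad.tolist()} have non-positive session maximum"
        )
    window = int(round(window_ms * fs / 1000.0))
    normalized = rectified / session_max[:, None]
    env = moving_rms(normalized, window)
    return EnvelopeMatrix(values=np.clip(env, 0.0, 1.0), fs_effective=fs)


def _smooth_angle(angle: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    window = max(int(round(smooth_ms * fs / 1000.0)), 1)
    kernel = np.ones(window) / window
    # shrink-to-valid moving average (same edge policy as the envelope)
    csum = np.concatenate([[0.0], np.cumsum(angle)])
    n = angle.size
    half_lo = (window - 1) // 2
    half_hi = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    del kernel
    return (csum[hi] - csum[lo]) / (hi - lo)


def segment_motion(
    angle: np.ndarray,
    fs: float,
    motion: str,
    *,
    smooth_ms: float = ANGLE_SMOOTH_MS,
    speed_threshold_frac: float = SPEED_THRESHOLD_FRAC,
) -> list[MotionSegment]:
    """Locate motion repetitions on the knee-angle trace.

    STD/ST: each repetition is a bell-shaped angle excursion.  Its start is
    the first sample whose absolute angular speed reaches 10% of the maximum
    speed of the initiating (pre-peak) phase; its end is the first sample
    after the terminal-phase speed peak where the absolute speed falls below
    10% of that phase's maximum.

    Gait: cycle boundaries are the first local angle minimum after each
    local maximum; segments span consecutive boundaries.

    Returns an empty list (with a logged warning) when no repetition is
    found.
    """
    angle = np.asarray(angle, dtype=float)
    if angle.size < fs:
        logger.warning("angle trace shorter than 1 s; no segmentation attempted")
        return []
    smoothed = _smooth_angle(angle, fs, smooth_ms)
    if np.ptp(smoothed) == 0:
        logger.warning("flat angle trace; no repetitions found")
        return []
    speed = np.gradient(smoothed) * fs

    if motion in ("STD", "ST"):
        return _segment_bells(smoothed, speed, fs, motion, speed_threshold_frac)
    return _segment_gait(smoothed, fs, motion)


def _segment_bells(
    smoothed: np.ndarray,
    speed: np.ndarray,
    fs: float,
    motion: str,
    frac: float,
) -> list[MotionSegment]:
    # Bell peaks: prominence >= 20% of the angle range, >= 1 s apart
    # (repetitions are separated by multi-second rests).
    rng_angle = np.ptp(smoothed)
    peaks, _ = signal.find_peaks(
        smoothed, prominence=0.2 * rng_angle, distance=int(fs)
    )
    if peaks.size == 0:
        logger.warning("no bell-shaped repetitions detected in %s trace", motion)
        return []
    # Hold phases make the excursion a plateau; anchor each repetition at the
    # midpoint of its plateau so initiating/terminal phases split cleanly.
    segments: list[MotionSegment] = []
    n = smoothed.size
    bounds = np.concatenate([[0], (peaks[:-1] + peaks[1:]) // 2, [n - 1]])
    abs_speed = np.abs(speed)
    for i, peak in enumerate(peaks):
        lo, hi = int(bounds[i]), int(bounds[i + 1])
        init_phase = abs_speed[lo:peak]
        term_phase = abs_speed[peak:hi]
        if init_phase.size == 0 or term_phase.size == 0:
            continue
        thr_init = frac * init_phase.max()
        above = np.flatnonzero(init_phase >= thr_init)
        if above.size == 0:
            continue
        start = lo + int(above[0])
        thr_term = frac * term_phase.max()
        term_peak = peak + int(np.argmax(term_phase))
        below = np.flatnonzero(abs_speed[term_peak:hi] < thr_term)
        end = term_peak + int(below[0]) if below.size else hi
        if end > start:
            segments.append(MotionSegment(start=start, end=end, motion=motion))
    if not segments:
        logger.warning("no valid repetitions in %s trace", motion)
    return segments


def _segment_gait(smoothed: np.ndarray, fs: float, motion: str) -> list[MotionSegment]:
    rng_angle = np.ptp(smoothed)
    min_cycle = int(0.4 * fs)  # physiological lower bound on a gait cycle
    maxima, _ = signal.find_peaks(
        smoothed, prominence=0.2 * rng_angle, distance=min_cycle
    )
    minima, _ = signal.find_peaks(
        -smoothed, prominence=0.2 * rng_angle, distance=min_cycle
    )
    if maxima.size == 0 or minima.size == 0:
        logger.warning("no gait cycles detected")
        return []
    # first minimum after each maximum -> cycle boundary
    boundaries = []
    for mx in maxima:
        after = minima[minima > mx]
        if after.size:
            b = int(after[0])
            if not boundaries or b != boundaries[-1]:
                boundaries.append(b)
    segments = [
        MotionSegment(start=boundaries[i], end=boundaries[i + 1], motion=motion)
        for i in range(len(boundaries) - 1)
    ]
    if not segments:
        logger.warning("fewer than two gait-cycle boundaries found")
    return segments


def resample_segment(envelope: np.ndarray, n_out: int = RESAMPLE_POINTS) -> np.ndarray:
    """Linearly resample an (m, L) envelope chunk to (m, n_out) columns.

    The uniform output grid runs from the first to the last input sample, so
    endpoints are preserved exactly and non-negativity is maintained.
    """
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    m, L = envelope.shape
    if L < 2:
        raise DegenerateSegmentError(f"segment of length {L} cannot be resampled")
    x_out = np.linspace(0.0, L - 1.0, n_out)
    x_in = np.arange(L, dtype=float)
    return np.vstack([np.interp(x_out, x_in, envelope[ch]) for ch in range(m)])


def attach_envelopes(
    segments: list[MotionSegment],
    envelope: EnvelopeMatrix,
    n_out: int = RESAMPLE_POINTS,
) -> list[MotionSegment]:
    """Fill each segment's ``envelope_resampled`` from the full envelope."""
    for seg in segments:
        seg.envelope_resampled = resample_segment(
            envelope.values[:, seg.start : seg.end], n_out
        )
    return segments
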