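"""Synthetic lower-limb sEMG cohorts with planted synergy structure.

Each generated recording follows the amplitude-modulation model of surface
EMG: a non-negative envelope ``E = W_true @ H_true`` (muscles x time)
multiplies a band-limited (20-450 Hz) zero-mean noise carrier, so that
rectify-then-smooth preprocessing recovers the planted envelope up to
scale.  The knee-angle channel is a sequence of bell-shaped excursions
(2 s rise, 2 s hold, 2 s fall, matching a slow flex-hold-extend movement)
separated by 3 s rests for the standing/sitting tasks, or a periodic trace
with one clear minimum per 1.32 s cycle for gait.

Planted synergy patterns are fixed per motion and distinct across motions;
study-group (SG) recordings perturb the patterns by a fixed per-motion
direction scaled by ``group_shift``, giving a controllable between-group
difference.  Per-subject jitter and per-repetition amplitude variability
keep recordings from being carbon copies.

Seeding: one root seed; each recording derives its own stream
deterministically from (seed, subject id, group, motion), so cohorts are
bit-reproducible and recordings are independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .io_dataset import (
    DEFAULT_CHANNELS,
    Manifest,
    ManifestEntry,
    Recording,
    write_manifest,
    write_recording,
)

GAIT_CYCLE_S = 1.32
BELL_RISE_S = 2.0
BELL_HOLD_S = 2.0
BELL_FALL_S = 2.0
REST_S = 3.0
LEAD_S = 2.0
ANGLE_AMPLITUDE_DEG = 70.0

# Planted muscle weightings (RF, FB, VM, SEM) per motion, one column per
# synergy, up to 4.  STD recruits knee flexors (FB, SEM) first; ST recruits
# extensors (RF, VM) first; gait mixes flexor, extensor and a hybrid pattern.
_BASE_W = {
    "STD": np.array(
        [
            [0.10, 0.75, 0.30, 0.55],
            [0.90, 0.05, 0.35, 0.25],
            [0.05, 0.80, 0.55, 0.30],
            [0.80, 0.10, 0.15, 0.65],
        ]
    ),
    "ST": np.array(
        [
            [0.90, 0.05, 0.45, 0.20],
            [0.05, 0.80, 0.25, 0.60],
            [0.85, 0.10, 0.60, 0.30],
            [0.10, 0.75, 0.20, 0.55],
        ]
    ),
    "Gait": np.array(
        [
            [0.90, 0.10, 0.15, 0.10],
            [0.10, 0.85, 0.10, 0.40],
            [0.15, 0.10, 0.95, 0.10],
            [0.10, 0.45, 0.15, 0.90],
        ]
    ),
}

# Fixed between-group perturbation directions (one per motion): the SG
# pattern is normalize(clip(W + group_shift * D, 0)).  Each direction
# redistributes weight *within* a pattern (e.g. between hamstring heads,
# or from vastus medialis onto rectus femoris), mimicking compensatory
# recruitment; it deliberately avoids blending one synergy toward another
# so the planted synergy count survives the shift.
_GROUP_DIRECTION = {
    "STD": np.array(
        [
            [0.0, 0.5, -0.3, 0.2],
            [-0.5, 0.1, 0.2, -0.3],
            [0.1, -0.5, 0.4, 0.1],
            [0.5, 0.0, -0.2, 0.3],
        ]
    ),
    "ST": np.array(
        [
            [-0.5, 0.0, 0.3, -0.2],
            [0.0, 0.5, -0.2, 0.3],
            [0.5, 0.0, -0.3, 0.2],
            [0.1, -0.5, 0.2, -0.3],
        ]
    ),
    "Gait": np.array(
        [
            [-0.3, 0.0, 0.0, 0.2],
            [0.2, -0.3, 0.2, -0.2],
            [0.0, 0.0, -0.3, 0.2],
            [0.0, 0.2, 0.0, -0.3],
        ]
    ),
}

DEFAULT_K_TRUE = {"STD": 2, "ST": 2, "Gait": 3}


@dataclass
class SynthSpec:
    """Parameters of a synthetic cohort.

    ``k_true`` may be a single planted synergy count for every motion or a
    mapping motion -> count; the default plants 2 synergies for the
    standing/sitting tasks and 3 for gait.  ``noise_sd`` scales additive
    envelope noise as a fraction of the envelope peak; ``group_shift``
    scales the fixed SG perturbation of the planted patterns;
    ``w_jitter`` adds per-subject pattern variability.
    """

    m: int = 4
    k_true: int | dict[str, int] = field(default_factory=lambda: dict(DEFAULT_K_TRUE))
    n_subjects: int = 5
    reps: int = 4
    fs: float = 1000.0
    noise_sd: float = 0.05
    group_shift: float = 0.9
    w_jitter: float = 0.05
    seed: int = 0

    def k_for(self, motion: str) -> int:
        k = self.k_true[motion] if isinstance(self.k_true, dict) else self.k_true
        if not 1 <= k <= self.m:
            raise ConfigurationError(f"k_true={k} must satisfy 1 <= k <= m={self.m}")
        return k

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        for motion in ("STD", "ST", "Gait"):
            self.k_for(motion)


def _recording_rng(spec: SynthSpec, subject_id: str, group: str, motion: str):
    key = [zlib.crc32(s.encode()) for s in (subject_id, group, motion)]
    return np.random.default_rng(np.random.SeedSequence([spec.seed, *key]))


def _unit_columns(W: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(W, axis=0)
    return W / np.where(norms > 0, norms, 1.0)


def planted_w(spec: SynthSpec, group: str, motion: str) -> np.ndarray:
    """The planted synergy pattern for a group x motion (before jitter)."""
    k = spec.k_for(motion)
    W = _BASE_W[motion][: spec.m, :k].copy()
    if group == "SG" and spec.group_shift != 0:
        W = np.clip(W + spec.group_shift * _GROUP_DIRECTION[motion][: spec.m, :k], 0, None)
    return _unit_columns(W)


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def _bell(fs: float) -> np.ndarray:
    """Angle bell: raised-cosine rise, hold, raised-cosine fall."""
    n_rise = int(BELL_RISE_S * fs)
    n_hold = int(BELL_HOLD_S * fs)
    n_fall = int(BELL_FALL_S * fs)
    rise = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / n_rise))
    fall = 0.5 * (1 + np.cos(np.pi * np.arange(n_fall) / n_fall))
    return np.concatenate([rise, np.ones(n_hold), fall])


def _bump(n: int, center_frac: float, width_frac: float) -> np.ndarray:
    """Raised-cosine bump of given relative width centered in [0, 1]."""
    t = np.arange(n) / max(n - 1, 1)
    x = (t - center_frac) / width_frac
    out = np.zeros(n)
    mask = np.abs(x) < 0.5
    out[mask] = 0.5 * (1 + np.cos(2 * np.pi * x[mask]))
    return out


def _bell_motion_truth(spec: SynthSpec, motion: str, rng) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Angle trace, activation rows and true segment spans for STD/ST."""
    fs = spec.fs
    k = spec.k_for(motion)
    n_bell = _bell(fs).size
    n_rest = int(REST_S * fs)
    n_lead = int(LEAD_S * fs)
    T = n_lead + spec.reps * n_bell + (spec.reps - 1) * n_rest + n_lead
    angle = np.zeros(T)
    H = np.zeros((k, T))
    spans: list[tuple[int, int]] = []
    bell = _bell(fs)
    # synergy 1 (agonist) stays active through the whole movement
    # (concentric rise, isometric hold, eccentric lowering); later synergies
    # are weaker transition bursts (co-contraction at onset/release),
    # keeping the planted rank genuine while the agonist dominates.
    profiles = [signal.windows.tukey(n_bell, alpha=0.4)]
    if k > 1:
        # antagonist: onset/release co-contraction bursts; kept disjoint
        # from the plateau's flat top so the factorization stays
        # identifiable within short epochs
        profiles.append(0.8 * (_bump(n_bell, 0.12, 0.3) + _bump(n_bell, 0.88, 0.3)))
    for extra, center in zip(range(k - 2), np.linspace(0.35, 0.65, max(k - 2, 1))):
        profiles.append(0.5 * _bump(n_bell, center, 0.3))
    for r in range(spec.reps):
        start = n_lead + r * (n_bell + n_rest)
        end = start + n_bell
        angle[start:end] = ANGLE_AMPLITUDE_DEG * bell
        amp = 0.8 + 0.4 * rng.random(k)  # per-repetition effort variability
        for i in range(k):
            H[i, start:end] += amp[i] * profiles[i]
        spans.append((start, end))
    return angle, H, spans


def _gait_truth(spec: SynthSpec, motion: str, rng) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Angle trace, activation rows and cycle spans for gait."""
    fs = spec.fs
    k = spec.k_for(motion)
    n_cycles = 4 * spec.reps  # four steps per leg per walking pass
    n_cycle = int(GAIT_CYCLE_S * fs)
    n_lead = int(LEAD_S * fs)
    T = 2 * n_lead + n_cycles * n_cycle
    t = np.arange(T) / fs
    angle = np.zeros(T)
    body = slice(n_lead, n_lead + n_cycles * n_cycle)
    tb = t[body] - t[body][0]
    # one clear maximum and one clear minimum per cycle
    angle[body] = 30.0 - 25.0 * np.cos(2 * np.pi * tb / GAIT_CYCLE_S)
    H = np.zeros((k, T))
    phases = np.linspace(0.15, 0.85, k)
    phase = (tb / GAIT_CYCLE_S) % 1.0
    for i in range(k):
        x = (phase - phases[i] + 0.5) % 1.0 - 0.5
        bump = np.where(np.abs(x) < 0.09, 0.5 * (1 + np.cos(2 * np.pi * x / 0.18)), 0.0)
        H[i, body] = bump
    # per-cycle amplitude variability
    spans = []
    for c in range(n_cycles):
        s = n_lead + c * n_cycle
        e = s + n_cycle
        H[:, s:e] *= (0.8 + 0.4 * rng.random(k))[:, None]
        spans.append((s, e))
    return angle, H, spans


def _carrier(T: int, fs: float, rng) -> np.ndarray:
    """Band-limited (20-450 Hz) zero-mean unit-RMS noise carrier."""
    white = rng.standard_normal(T)
    sos = signal.butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, white)
    return band / max(np.sqrt(np.mean(band**2)), 1e-12)


def generate_recording(
    spec: SynthSpec, subject_id: str, group: str, motion: str
) -> tuple[Recording, dict]:
    """Generate one recording plus its ground truth.

    Returns ``(recording, truth)`` where ``truth`` holds the planted
    ``W_true`` (unit columns, after subject jitter), the full-length
    activation rows ``H_true``, and the true movement spans (half-open
    sample ranges).  Identical arguments always produce bit-identical
    output.
    """
    rng = _recording_rng(spec, subject_id, group, motion)
    W = planted_w(spec, group, motion)
    if spec.w_jitter > 0:
        W = _unit_columns(
            np.clip(W + spec.w_jitter * rng.standard_normal(W.shape), 0, None)
        )
    if motion in ("STD", "ST"):
        angle, H, spans = _bell_motion_truth(spec, motion, rng)
    else:
        angle, H, spans = _gait_truth(spec, motion, rng)
    T = angle.size
    envelope = W @ H
    if spec.noise_sd > 0:
        peak = envelope.max() if envelope.max() > 0 else 1.0
        envelope = np.clip(
            envelope + spec.noise_sd * peak * rng.standard_normal(envelope.shape), 0, None
        )
    semg = np.vstack([envelope[ch] * _carrier(T, spec.fs, rng) for ch in range(spec.m)])
    rec = Recording(
        semg=semg,
        angle=angle,
        fs=spec.fs,
        subject_id=subject_id,
        group=group,
        motion=motion,
        channel_names=list(DEFAULT_CHANNELS[: spec.m]),
    )
    truth = {"W_true": W, "H_true": H, "spans": spans}
    return rec, truth


def generate_cohort(
    spec: SynthSpec,
    groups: tuple[str, ...] = ("CG", "SG"),
    motions: tuple[str, ...] = ("STD", "ST", "Gait"),
) -> list[tuple[Recording, dict]]:
    """Generate all subject x group x motion recordings in memory."""
    out = []
    for group in groups:
        for s in range(spec.n_subjects):
            subject_id = f"{group}{s + 1:02d}"
            for motion in motions:
                out.append(generate_recording(spec, subject_id, group, motion))
    return out


def write_cohort(
    spec: SynthSpec,
    outdir: str | Path,
    groups: tuple[str, ...] = ("CG", "SG"),
    motions: tuple[str, ...] = ("STD", "ST", "Gait"),
) -> Path:
    """Write a cohort as delimited text plus a YAML manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    layout = {name: i for i, name in enumerate(DEFAULT_CHANNELS[: spec.m])}
    layout["angle"] = spec.m
    for rec, _ in generate_cohort(spec, groups, motions):
        fname = f"{rec.subject_id}_{rec.motion}.csv"
        write_recording(rec, outdir / fname)
        entries.append(
            ManifestEntry(
                path=fname,
                subject_id=rec.subject_id,
                group=rec.group,
                motion=rec.motion,
            )
        )
    manifest = Manifest(entries=entries, layout=layout, fs=spec.fs, root=outdir)
    path = outdir / "manifest.yaml"
    write_manifest(manifest, path)
    return path
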