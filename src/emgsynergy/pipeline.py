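"""End-to-end workflows built from the module-level operations.

These helpers wire the stages together the way the analyses use them:

* envelope preprocessing with per-subject session normalization,
* angle-driven segmentation and per-segment NMF (synergy-number selection,
  representative synergies, similarity tables),
* sliding-window NMF feature tables for motion and pathology
  classification.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from . import preprocess, synergy
from .features import extract_features, feature_names, reorder_by_activation_ratio, window_stream
from .io_dataset import Recording
from .preprocess import EnvelopeMatrix
from .similarity import build_representative, outlier_mask

logger = logging.getLogger(__name__)

# Restart count used for the per-window/per-segment factorizations driven
# by these workflows.  The full multi-restart default of nmf_decompose is
# kept for one-off decompositions; batch runs use fewer restarts since the
# 4 x n problems converge to the same optimum almost always.
BATCH_RESTARTS = 3


def rectify_cohort(recordings: list[Recording]) -> dict[str, np.ndarray]:
    """Rectified sEMG per recording id, keyed by (subject, motion)."""
    return {
        (rec.subject_id, rec.motion): np.vstack(
            [preprocess.filter_and_rectify(ch, rec.fs) for ch in rec.semg]
        )
        for rec in recordings
    }


def cohort_envelopes(recordings: list[Recording]) -> dict[tuple[str, str], EnvelopeMatrix]:
    """Envelopes for a cohort, normalized per subject across all motions."""
    rectified = rectify_cohort(recordings)
    by_subject: dict[str, list[np.ndarray]] = defaultdict(list)
    for (subject, _), r in rectified.items():
        by_subject[subject].append(r)
    maxima = {s: preprocess.session_maxima(rs) for s, rs in by_subject.items()}
    return {
        (rec.subject_id, rec.motion): preprocess.normalize_and_envelope(
            rectified[(rec.subject_id, rec.motion)],
            rec.fs,
            session_max=maxima[rec.subject_id],
        )
        for rec in recordings
    }


def segment_cohort(
    recordings: list[Recording],
    envelopes: dict[tuple[str, str], EnvelopeMatrix],
) -> dict[tuple[str, str], list[np.ndarray]]:
    """Per-recording resampled (m x 100) segment envelopes."""
    out: dict[tuple[str, str], list[np.ndarray]] = {}
    for rec in recordings:
        key = (rec.subject_id, rec.motion)
        segs = preprocess.segment_motion(rec.angle, rec.fs, rec.motion)
        preprocess.attach_envelopes(segs, envelopes[key])
        out[key] = [s.envelope_resampled for s in segs]
    return out


def select_k_per_motion(
    segments_by_key: dict[tuple[str, str], list[np.ndarray]],
    *,
    vaf_threshold: float = synergy.VAF_THRESHOLD,
    n_restarts: int = BATCH_RESTARTS,
    seed: int = 0,
) -> dict[str, int]:
    """Optimal synergy count per motion over all subjects' segments."""
    pooled: dict[str, list[np.ndarray]] = defaultdict(list)
    for (_, motion), segs in segments_by_key.items():
        pooled[motion].extend(segs)
    return {
        motion: synergy.select_synergy_number(
            segs,
            vaf_threshold=vaf_threshold,
            n_random_restarts=n_restarts,
            rng=seed,
        )
        for motion, segs in pooled.items()
    }


def mean_vaf_per_motion(
    segments_by_key: dict[tuple[str, str], list[np.ndarray]],
    k_values: tuple[int, ...] = (1, 2, 3),
    *,
    n_restarts: int = BATCH_RESTARTS,
    seed: int = 0,
) -> dict[str, dict[int, float]]:
    """Mean VAF across segments per motion for each candidate k."""
    pooled: dict[str, list[np.ndarray]] = defaultdict(list)
    for (_, motion), segs in segments_by_key.items():
        pooled[motion].extend(segs)
    rng = np.random.default_rng(seed)
    table: dict[str, dict[int, float]] = {}
    for motion, segs in pooled.items():
        table[motion] = {}
        for k in k_values:
            vafs = [
                synergy.nmf_decompose(s, k, n_random_restarts=n_restarts, rng=rng).vaf
                for s in segs
            ]
            table[motion][k] = float(np.mean(vafs))
    return table


def representative_synergies(
    segments_by_key: dict[tuple[str, str], list[np.ndarray]],
    k_per_motion: dict[str, int],
    *,
    n_restarts: int = BATCH_RESTARTS,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], tuple[np.ndarray, np.ndarray]], int, int]:
    """Per subject x motion representative (W, H) plus outlier bookkeeping.

    Decomposes every segment at the motion's synergy count, removes outlier
    pattern matrices by the 3-sigma similarity rule, and averages.
    Returns ``(reps, n_outliers, n_matrices)``.
    """
    rng = np.random.default_rng(seed)
    reps: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    n_out = 0
    n_tot = 0
    for key, segs in segments_by_key.items():
        if len(segs) < 2:
            logger.warning("key %s has %d segments; skipped", key, len(segs))
            continue
        k = k_per_motion[key[1]]
        ws = [
            synergy.nmf_decompose(s, k, n_random_restarts=n_restarts, rng=rng).W
            for s in segs
        ]
        n_tot += len(ws)
        n_out += int(outlier_mask(ws).sum())
        W_rep, H_rep = build_representative(ws, segs)
        reps[key] = (W_rep, H_rep)
    return reps, n_out, n_tot


def build_feature_table(
    recordings: list[Recording],
    *,
    k: int = 2,
    feature_set: str = "fine",
    label_by: str = "motion",
    n_restarts: int = BATCH_RESTARTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Sliding-window NMF feature table for a cohort.

    Each 256-sample envelope window is factored at the given synergy count,
    synergies are reordered by activation ratio, and the requested feature
    set is extracted.  ``label_by`` selects the class label column:
    ``"motion"`` for motion recognition, ``"group"`` for pathology status.
    Returns a DataFrame with named feature columns plus ``label``,
    ``subject_id``, ``group`` and ``motion``.
    """
    if label_by not in ("motion", "group"):
        raise ValueError(f"label_by must be 'motion' or 'group', got {label_by!r}")
    envelopes = cohort_envelopes(recordings)
    rng = np.random.default_rng(seed)
    rows = []
    for rec in recordings:
        env = envelopes[(rec.subject_id, rec.motion)]
        # window only the movement spans: rest periods carry no muscle
        # activity and would dilute every class with noise-only epochs
        spans = preprocess.segment_motion(rec.angle, rec.fs, rec.motion)
        if spans:
            windows = [
                w
                for seg in spans
                for w in window_stream(env.values[:, seg.start : seg.end])
            ]
        else:
            windows = window_stream(env.values)
        for win in windows:
            dec = synergy.nmf_decompose(win, k, n_random_restarts=n_restarts, rng=rng)
            W_s, H_s, _ = reorder_by_activation_ratio(dec.W, dec.H)
            label = rec.motion if label_by == "motion" else rec.group
            fr = extract_features(W_s, H_s, feature_set, label=label)
            row = fr.as_dict()
            row["label"] = label
            row["subject_id"] = rec.subject_id
            row["group"] = rec.group
            row["motion"] = rec.motion
            rows.append(row)
    cols = feature_names(recordings[0].n_channels, k, feature_set)
    return pd.DataFrame(rows, columns=cols + ["label", "subject_id", "group", "motion"])
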