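"""Windowing and feature extraction from per-window synergy decompositions.

The continuous envelope is cut into 256-sample windows that share 64
samples with their neighbours (step 192).  Each window is factored by NMF;
because NMF column order is arbitrary, synergies are reordered by their
activation ratio

    r_i = RMS(h_i) / sum_j RMS(h_j)

from largest to smallest before features are read off.

Two feature sets exist per window:

* coarse — the muscle weights of the reordered synergy pattern matrix,
  ``W11..W1m, ..., Wk1..Wkm`` (4k values for m = 4 muscles);
* fine — coarse plus eight time-domain descriptors of every reordered
  activation row: RMS, the four coefficients of a 4th-order autoregressive
  model (named AR2..AR5), interquartile range, waveform length and mean
  absolute value (4k + 8k values).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import burg

from .errors import DomainError

logger = logging.getLogger(__name__)

WINDOW_SAMPLES = 256
OVERLAP_SAMPLES = 64
AR_ORDER = 4
_H_STAT_NAMES = ("rms", "AR2", "AR3", "AR4", "AR5", "IQR", "WL", "MAV")


@dataclass
class FeatureRecord:
    """Named, ordered feature vector for one window plus its class label."""

    values: np.ndarray
    names: list[str]
    label: str
    k_used: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def window_stream(
    envelope: np.ndarray,
    window: int = WINDOW_SAMPLES,
    overlap: int = OVERLAP_SAMPLES,
) -> list[np.ndarray]:
    """Cut an (m, T) envelope into windows of ``window`` samples.

    Consecutive windows share ``overlap`` samples, i.e. starts advance by
    ``window - overlap``.  A trailing partial window is discarded; an
    envelope shorter than one window yields an empty list with a warning.
    """
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    T = envelope.shape[1]
    if T < window:
        logger.warning("envelope of %d samples shorter than window %d", T, window)
        return []
    step = window - overlap
    starts = range(0, T - window + 1, step)
    return [envelope[:, s : s + window] for s in starts]


def reorder_by_activation_ratio(
    W: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort synergies by descending activation ratio.

    Returns ``(W', H', r)`` with r the sorted activation ratios.  The
    column of W and row of H of each synergy move together, so the
    reconstruction W @ H is unchanged.  Ties keep their original order.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    H = np.atleast_2d(np.asarray(H, dtype=float))
    rms = np.sqrt(np.mean(H**2, axis=1))
    total = rms.sum()
    if total == 0:
        raise DomainError("activation ratios undefined: H is all-zero")
    r = rms / total
    order = np.argsort(-r, kind="stable")
    return W[:, order], H[order, :], r[order]


def _ar_coefficients(h: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Coefficients a_1..a_4 of  h_t = -sum_i a_i h_{t-i} + e_t  (Burg fit).

    A (near-)constant activation row has no AR structure; zeros are
    returned with a warning.
    """
    h = np.asarray(h, dtype=float)
    if h.size <= order or np.ptp(h) == 0 or np.var(h) < 1e-24:
        logger.warning("degenerate activation row: AR coefficients set to 0")
        return np.zeros(order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            rho, _ = burg(h, order=order, demean=True)
        except (ValueError, np.linalg.LinAlgError):
            logger.warning("AR fit failed: coefficients set to 0")
            return np.zeros(order)
    if not np.all(np.isfinite(rho)):
        logger.warning("AR fit non-finite: coefficients set to 0")
        return np.zeros(order)
    return -np.asarray(rho)


def activation_stats(h: np.ndarray) -> dict[str, float]:
    """The eight time-domain descriptors of one activation row."""
    h = np.asarray(h, dtype=float)
    n = h.size
    rms = float(np.sqrt(np.mean(h**2)))
    ar = _ar_coefficients(h)
    q1, q3 = np.percentile(h, [25, 75])  # linear-interpolation quartiles
    iqr = float(q3 - q1)
    wl = float(np.sum(np.abs(np.diff(h)))) if n > 1 else 0.0
    mav = float(np.mean(np.abs(h)))
    out = {"rms": rms, "IQR": iqr, "WL": wl, "MAV": mav}
    for i, name in enumerate(("AR2", "AR3", "AR4", "AR5")):
        out[name] = float(ar[i])
    return out


def feature_names(m: int, k: int, feature_set: str) -> list[str]:
    """Ordered feature names for m muscles and k synergies."""
    names = [f"W{i + 1}{j + 1}" for i in range(k) for j in range(m)]
    if feature_set == "fine":
        for i in range(k):
            names.extend(f"{stat}{i + 1}" for stat in _H_STAT_NAMES)
    elif feature_set != "coarse":
        raise DomainError(f"unknown feature set {feature_set!r}")
    return names


def extract_features(
    W_sorted: np.ndarray,
    H_sorted: np.ndarray,
    feature_set: str = "fine",
    label: str = "",
) -> FeatureRecord:
    """Build the feature vector from a reordered (W, H) pair.

    ``coarse`` flattens W synergy-major (all muscle weights of synergy 1,
    then synergy 2, ...).  ``fine`` appends, per activation row, RMS, the
    four AR coefficients, IQR, waveform length and mean absolute value.
    Feature name ``W{i}{j}`` is the weight of muscle j in synergy i; the
    activation descriptors carry the synergy index as suffix (e.g. ``AR21``
    is the first AR coefficient of synergy 1's activation).
    """
    W_sorted = np.atleast_2d(np.asarray(W_sorted, dtype=float))
    H_sorted = np.atleast_2d(np.asarray(H_sorted, dtype=float))
    m, k = W_sorted.shape
    values = list(W_sorted.T.ravel())
    if feature_set == "fine":
        for i in range(k):
            stats = activation_stats(H_sorted[i])
            values.extend(stats[name] for name in _H_STAT_NAMES)
    elif feature_set != "coarse":
        raise DomainError(f"unknown feature set {feature_set!r}")
    return FeatureRecord(
        values=np.asarray(values, dtype=float),
        names=feature_names(m, k, feature_set),
        label=label,
        k_used=k,
    )
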