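"""Similarity of synergy matrices and representative-synergy construction.

Two synergy pattern matrices are compared by their *maximum correlation
coefficient* (max CC): with k1 <= k2, every ordered selection of k1 columns
from the larger matrix is assembled into a candidate matrix, the Pearson
correlation between the column-stacked vectorizations is computed, and the
largest value wins.  Enumerating ordered selections makes the column
correspondence part of the maximization, which is feasible because k never
exceeds the channel count (4 here).

The same score defines intra-group similarity (mean over all within-group
pairs) and inter-group similarity (mean over the full cross-product of
pairs), for synergy pattern matrices and activation-coefficient matrices
alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

from .errors import DomainError, UndefinedStatisticError
from .synergy import estimate_activation


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise UndefinedStatisticError(
            "correlation undefined: constant matrix after vectorization"
        )
    return float(np.dot(xc, yc) / (nx * ny))


def _max_cc_with_perm(W1: np.ndarray, W2: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Max CC and the winning ordered column selection from W2 (k1 <= k2)."""
    k1, k2 = W1.shape[1], W2.shape[1]
    v1 = W1.ravel(order="F")
    best_cc, best_sel = -np.inf, None
    for sel in permutations(range(k2), k1):
        cc = _pearson(v1, W2[:, sel].ravel(order="F"))
        if cc > best_cc:
            best_cc, best_sel = cc, sel
    assert best_sel is not None
    return best_cc, best_sel


def max_cc(W1: np.ndarray, W2: np.ndarray) -> float:
    """Maximum correlation coefficient between two synergy matrices.

    Matrices must share the row (muscle) count; column counts may differ.
    Raises :class:`UndefinedStatisticError` when either vectorized matrix is
    constant (zero variance).
    """
    W1 = np.atleast_2d(np.asarray(W1, dtype=float))
    W2 = np.atleast_2d(np.asarray(W2, dtype=float))
    if W1.shape[0] != W2.shape[0]:
        raise DomainError(
            f"row mismatch: {W1.shape[0]} vs {W2.shape[0]} muscles"
        )
    if W1.shape[1] > W2.shape[1]:
        W1, W2 = W2, W1
    return _max_cc_with_perm(W1, W2)[0]


@dataclass
class SimilarityReport:
    """Intra- and inter-group mean max-CC values.

    ``intra`` maps group label -> mean over all unordered within-group
    pairs; ``inter`` maps (label_a, label_b) -> mean over the full
    cross-product of pairs; ``pairwise`` keeps the underlying per-pair
    values for export.
    """

    intra: dict[str, float]
    inter: dict[tuple[str, str], float]
    pairwise: dict[tuple[str, str], np.ndarray]


def group_similarity(groups: dict[str, list[np.ndarray]]) -> SimilarityReport:
    """Intra-similarity per group and inter-similarity per group pair.

    Every group needs >= 2 matrices for its intra score (a singleton group
    raises :class:`DomainError`); inter scores need >= 1 matrix per group.
    Applies unchanged to activation-coefficient matrices.
    """
    intra: dict[str, float] = {}
    pairwise: dict[tuple[str, str], np.ndarray] = {}
    for label, mats in groups.items():
        if len(mats) < 2:
            raise DomainError(
                f"group {label!r} has {len(mats)} matrix; intra-similarity needs >= 2"
            )
        vals = np.array([max_cc(a, b) for a, b in combinations(mats, 2)])
        intra[label] = float(vals.mean())
        pairwise[(label, label)] = vals
    inter: dict[tuple[str, str], float] = {}
    for la, lb in combinations(groups, 2):
        vals = np.array(
            [max_cc(a, b) for a in groups[la] for b in groups[lb]]
        )
        inter[(la, lb)] = float(vals.mean())
        pairwise[(la, lb)] = vals
    return SimilarityReport(intra=intra, inter=inter, pairwise=pairwise)


def build_representative(
    matrices: list[np.ndarray],
    segments: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Representative (W, H) for one subject x motion.

    Steps: (1) score each matrix by its mean max CC against all others;
    (2) drop matrices whose score deviates from the group mean by 3 standard
    deviations or more (when the scores have zero spread nothing is
    dropped); (3) align each survivor's columns to the first survivor by the
    max-CC column correspondence, average element-wise, and renormalize the
    columns; (4) when segment envelopes are given, re-estimate each
    segment's activation under the representative W and average them.

    Returns ``(W_rep, H_rep)``; ``H_rep`` is None when no segments are
    supplied.  All segment envelopes must share one column count (segments
    are resampled to a common length upstream).
    """
    if len(matrices) < 2:
        raise DomainError("need >= 2 matrices to build a representative synergy")
    mats = [np.atleast_2d(np.asarray(Wi, dtype=float)) for Wi in matrices]
    n = len(mats)
    scores = np.array(
        [np.mean([max_cc(mats[i], mats[j]) for j in range(n) if j != i]) for i in range(n)]
    )
    mean_s, sd_s = scores.mean(), scores.std()
    if sd_s == 0:
        keep = np.arange(n)
    else:
        keep = np.flatnonzero(np.abs(scores - mean_s) < 3 * sd_s)
    if keep.size == 0:  # unreachable under the 3-sigma rule, but guarded
        raise DomainError("outlier rule removed every matrix")

    survivors = [mats[i] for i in keep]
    ref = survivors[0]
    aligned = [ref]
    for Wi in survivors[1:]:
        _, sel = _max_cc_with_perm(ref, Wi)
        aligned.append(Wi[:, sel])
    W_rep = np.mean(aligned, axis=0)
    norms = np.linalg.norm(W_rep, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    W_rep = W_rep / norms

    H_rep = None
    if segments is not None:
        if not segments:
            raise DomainError("segment list is empty")
        hs = [estimate_activation(seg, W_rep) for seg in segments]
        H_rep = np.mean(hs, axis=0)
    return W_rep, H_rep


def outlier_mask(matrices: list[np.ndarray]) -> np.ndarray:
    """Boolean mask of matrices flagged as outliers by the 3-sigma rule."""
    mats = [np.atleast_2d(np.asarray(Wi, dtype=float)) for Wi in matrices]
    n = len(mats)
    if n < 2:
        return np.zeros(n, dtype=bool)
    scores = np.array(
        [np.mean([max_cc(mats[i], mats[j]) for j in range(n) if j != i]) for i in range(n)]
    )
    sd_s = scores.std()
    if sd_s == 0:
        return np.zeros(n, dtype=bool)
    return np.abs(scores - scores.mean()) >= 3 * sd_s
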