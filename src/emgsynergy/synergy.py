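"""Muscle-synergy extraction by non-negative matrix factorization.

An envelope matrix ``A`` (m channels x n samples) is factored as
``A ~ W @ H`` with ``W`` (m x k) the synergy pattern matrix — each column a
fixed, non-negative muscle weighting — and ``H`` (k x n) the activation
coefficients.  The factorization minimizes the Euclidean (Frobenius) cost
``J = ||A - W H||`` with the Lee-Seung multiplicative updates:

    H <- H * (W^T A) / (W^T W H)
    W <- W * (A H^T) / (W H H^T)

After every iteration each column of W is rescaled to unit Euclidean norm
and the matching row of H by the inverse factor, so the product W H is
unchanged while synergy patterns stay comparable across subjects.  To avoid
poor local minima the factorization is restarted from 20 random
initializations plus one SVD-based (NNDSVD-style) initialization, and the
run with the highest VAF wins.

VAF (variability accounted for) is

    VAF = 1 - ||A - W H||_F^2 / ||A - mean(A)||_F^2 .

The number of synergies per motion is the smallest k whose mean VAF over
all motion segments exceeds 0.85.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, OrderError, UndefinedStatisticError

logger = logging.getLogger(__name__)

N_RANDOM_RESTARTS = 20
MAX_ITER = 1000
TOL = 1e-6
VAF_THRESHOLD = 0.85
_EPS = 1e-12


@dataclass
class SynergyDecomposition:
    """Result of one NMF factorization.

    ``W`` has non-negative, unit-L2-norm columns; ``H`` is non-negative.
    ``init_kind`` records which restart won ('random' or 'svd');
    ``cost_trace`` holds the Euclidean cost after every iteration of the
    winning run.
    """

    W: np.ndarray
    H: np.ndarray
    vaf: float
    k: int
    init_kind: str
    iterations_run: int
    cost_trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def compute_vaf(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Variability accounted for by the reconstruction W @ H.

    Raises
    ------
    UndefinedStatisticError
        If A is constant (zero total sum of squares about its grand mean).
    """
    A = np.asarray(A, dtype=float)
    resid = A - W @ H
    total = A - A.mean()
    denom = float(np.sum(total**2))
    if denom == 0.0:
        raise UndefinedStatisticError("VAF undefined: A is constant")
    return 1.0 - float(np.sum(resid**2)) / denom


def _update_h(A, W, H):
    return H * (W.T @ A) / (W.T @ W @ H + _EPS)


def _update_w(A, W, H):
    return W * (A @ H.T) / (W @ H @ H.T + _EPS)


def _normalize_columns(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-L2 columns of W with compensating H-row rescale (W@H unchanged)."""
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    return W / norms, H * norms[:, None]


def _run_mu(A, W, H, max_iter, tol, *, update_w=True):
    """Multiplicative updates until the relative cost decrease drops below tol."""
    cost_prev = np.linalg.norm(A - W @ H)
    trace = [cost_prev]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        H = _update_h(A, W, H)
        if update_w:
            W = _update_w(A, W, H)
            W, H = _normalize_columns(W, H)
        cost = np.linalg.norm(A - W @ H)
        trace.append(cost)
        if cost_prev > 0 and (cost_prev - cost) / cost_prev < tol:
            cost_prev = cost
            break
        cost_prev = cost
    return W, H, iterations, np.asarray(trace)


def _nndsvd_init(A: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization.

    Negative parts are zeroed; remaining zeros are replaced by a small
    positive constant (mean(A) * 1e-3) so multiplicative updates can move
    every entry.
    """
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    m, n = A.shape
    W = np.zeros((m, k))
    H = np.zeros((k, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, min(k, S.size)):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            x, y = up / max(n_up, _EPS), vp / max(n_vp, _EPS)
        else:
            sigma = n_un * n_vn
            x, y = un / max(n_un, _EPS), vn / max(n_vn, _EPS)
        W[:, j] = np.sqrt(S[j] * sigma) * x
        H[j, :] = np.sqrt(S[j] * sigma) * y
    floor = max(A.mean() * 1e-3, _EPS)
    W[W <= 0] = floor
    H[H <= 0] = floor
    return W, H


def nmf_decompose(
    A: np.ndarray,
    k: int,
    *,
    n_random_restarts: int = N_RANDOM_RESTARTS,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    rng: np.random.Generator | int | None = None,
) -> SynergyDecomposition:
    """Factor an envelope matrix into k synergies, best of multiple restarts.

    Runs ``n_random_restarts`` multiplicative-update optimizations from
    uniform-random initial (W, H) plus one from an NNDSVD initialization,
    and returns the run with maximal VAF (ties broken by run order, the
    SVD run last, so results are deterministic given ``rng``).

    Raises
    ------
    DomainError   if A has negative entries.
    OrderError    if k exceeds the channel count or k < 1.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    m, _ = A.shape
    if np.any(A < 0):
        raise DomainError("envelope matrix must be non-negative")
    if not 1 <= k <= m:
        raise OrderError(f"synergy count k={k} must satisfy 1 <= k <= m={m}")
    rng = np.random.default_rng(rng)

    scale = max(np.sqrt(A.mean() / max(k, 1)), _EPS)
    best: SynergyDecomposition | None = None
    inits: list[tuple[str, np.ndarray, np.ndarray]] = []
    for _ in range(n_random_restarts):
        # uniform on (0, 1], scaled to the data magnitude
        W0 = (1.0 - rng.random((m, k))) * scale
        H0 = (1.0 - rng.random((k, A.shape[1]))) * scale
        inits.append(("random", W0, H0))
    inits.append(("svd", *_nndsvd_init(A, k)))

    for init_kind, W0, H0 in inits:
        W0, H0 = _normalize_columns(W0, H0)
        W, H, iters, trace = _run_mu(A, W0, H0, max_iter, tol)
        try:
            vaf = compute_vaf(A, W, H)
        except UndefinedStatisticError:
            vaf = -np.inf
        if best is None or vaf > best.vaf:
            best = SynergyDecomposition(
                W=W, H=H, vaf=vaf, k=k, init_kind=init_kind,
                iterations_run=iters, cost_trace=trace,
            )
    assert best is not None
    return best


def estimate_activation(
    A: np.ndarray,
    W_fixed: np.ndarray,
    *,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> np.ndarray:
    """Estimate activation coefficients for a fixed synergy pattern matrix.

    Only the H multiplicative update runs; W is never modified.  H starts
    uniformly positive at the scale of A.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    W_fixed = np.atleast_2d(np.asarray(W_fixed, dtype=float))
    if W_fixed.shape[0] != A.shape[0]:
        raise OrderError(
            f"W has {W_fixed.shape[0]} rows but A has {A.shape[0]} channels"
        )
    if np.any(W_fixed < 0):
        raise DomainError("W_fixed must be non-negative")
    k = W_fixed.shape[1]
    H0 = np.full((k, A.shape[1]), max(A.mean(), _EPS))
    _, H, _, _ = _run_mu(A, W_fixed.copy(), H0, max_iter, tol, update_w=False)
    return H


def select_synergy_number(
    segments: list[np.ndarray],
    *,
    vaf_threshold: float = VAF_THRESHOLD,
    k_max: int | None = None,
    n_random_restarts: int = N_RANDOM_RESTARTS,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Smallest k whose mean VAF over all segments exceeds the threshold.

    Decomposes every segment envelope at k = 1..k_max and averages the VAF
    across segments.  Falls back to ``k_max`` (with a warning) when no k
    qualifies.
    """
    if not segments:
        raise DomainError("segment list is empty")
    m = np.atleast_2d(segments[0]).shape[0]
    if k_max is None:
        k_max = m
    rng = np.random.default_rng(rng)
    for k in range(1, k_max + 1):
        vafs = [
            nmf_decompose(
                seg, k, n_random_restarts=n_random_restarts,
                max_iter=max_iter, tol=tol, rng=rng,
            ).vaf
            for seg in segments
        ]
        if float(np.mean(vafs)) > vaf_threshold:
            return k
    logger.warning(
        "no synergy count up to %d reached mean VAF > %.2f; returning %d",
        k_max, vaf_threshold, k_max,
    )
    return k_max
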