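"""Two-stage feature selection: Relief-F screening, then a floating wrapper search.

Stage 1 ranks features with Relief-F.  The weight of feature A is updated
once per sample R (the iteration count equals the sample count, no
subsampling), with k = 1 nearest neighbours:

    RI(A) <- RI(A) - sum_j diff(A, R, H_j) / (m k)
             + sum_{C != class(R)} [p(C) / (1 - p(class(R)))]
               * sum_j diff(A, R, M_{j,C}) / (m k)

where H_j are the nearest hits (same class), M_{j,C} the nearest misses in
class C, p(C) the empirical class prior, and

    diff(A, B, C) = |B_A - C_A| / (max(A) - min(A)) ,

defined as 0 for a constant feature.  Features with negative weight are
eliminated.

Stage 2 runs a sequential floating forward search (SFFS) over the
survivors: repeatedly add the feature that most improves a wrapper score,
then conditionally drop any already-selected feature whose removal improves
it further.  The default wrapper scores a candidate subset by the mean
macro F-measure of a 30-tree random forest under internal stratified
5-fold cross-validation with a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .classify import f_measure_report
from .errors import DomainError

logger = logging.getLogger(__name__)

K_NEIGHBORS = 1
SFFS_PATIENCE = 3
WRAPPER_FOLDS = 5
WRAPPER_TREES = 30


@dataclass
class SelectionResult:
    """Outcome of the two-stage selection."""

    ri: dict[str, float]
    stage1_kept: list[str]
    stage2_selected: list[str]
    wrapper_scores: list[float] = field(default_factory=list)


def relieff_weights(
    X: np.ndarray, y: Sequence, k_neighbors: int = K_NEIGHBORS
) -> np.ndarray:
    """Relief-F weight per feature (vectorized over features).

    Iterates over every sample; nearest hits/misses are found with the
    Manhattan distance on range-normalized features, ties broken by the
    lowest sample index.  Constant features keep weight 0 exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DomainError("Relief-F needs >= 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt < k_neighbors + 1:
            raise DomainError(
                f"class {cls!r} has {cnt} samples; needs >= {k_neighbors + 1}"
            )
    priors = dict(zip(classes, counts / n))

    rng_feat = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng_feat > 0, rng_feat, 1.0)
    Xn = (X - X.min(axis=0)) / scale
    Xn[:, rng_feat == 0] = 0.0  # constant feature: diff == 0 everywhere

    m = n  # iteration count = sample count
    ri = np.zeros(p)
    for r in range(n):
        dist = np.sum(np.abs(Xn - Xn[r]), axis=1)
        dist[r] = np.inf
        order = np.argsort(dist, kind="stable")
        same = y[order] == y[r]
        hits = order[same][:k_neighbors]
        ri -= np.abs(Xn[hits] - Xn[r]).sum(axis=0) / (m * k_neighbors)
        denom = 1.0 - priors[y[r]]
        for cls in classes:
            if cls == y[r]:
                continue
            misses = order[y[order] == cls][:k_neighbors]
            ri += (
                priors[cls] / denom
            ) * np.abs(Xn[misses] - Xn[r]).sum(axis=0) / (m * k_neighbors)
    return ri


def make_rf_evaluator(
    seed: int,
    n_folds: int = WRAPPER_FOLDS,
    n_trees: int = WRAPPER_TREES,
) -> Callable[[np.ndarray, np.ndarray], float]:
    """Wrapper score: mean macro F-measure of a small random forest under
    internal stratified cross-validation (deterministic given seed)."""

    def evaluate(X: np.ndarray, y: np.ndarray) -> float:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        classes = np.unique(y)
        fms = []
        for tr, te in skf.split(X, y):
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt", random_state=seed
            )
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            conf = _confusion(y[te], pred, classes)
            _, _, fm = f_measure_report(conf)
            fms.append(float(np.mean(fm)))
        return float(np.mean(fms))

    return evaluate


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, pr in zip(y_true, y_pred):
        conf[idx[t], idx[pr]] += 1
    return conf


def sffs_select(
    X: np.ndarray,
    y: Sequence,
    candidate_features: Sequence[str],
    evaluator: Callable[[np.ndarray, np.ndarray], float],
    *,
    patience: int = SFFS_PATIENCE,
) -> tuple[list[str], list[float]]:
    """Sequential floating forward selection over named feature columns.

    ``X`` columns correspond to ``candidate_features`` in order.  Returns
    the best-scoring subset found (in selection order) and the score trace.
    Forward ties break by feature-name order; the search stops after
    ``patience`` consecutive additions fail to improve the best score.
    An evaluator failure scores the subset 0 (logged).
    """
    names = list(candidate_features)
    if not names:
        return [], []
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    col = {nm: i for i, nm in enumerate(names)}

    def score(subset: list[str]) -> float:
        if not subset:
            return -np.inf
        try:
            return evaluator(X[:, [col[s] for s in subset]], y)
        except Exception as exc:  # evaluator contract: never abort the search
            logger.warning("evaluator failed on %s: %s", subset, exc)
            return 0.0

    selected: list[str] = []
    best_set: list[str] = []
    best_score = -np.inf
    trace: list[float] = []
    stall = 0
    while stall < patience and len(selected) < len(names):
        # forward step: best single addition, ties by name order
        remaining = sorted(set(names) - set(selected))
        add_score, add_name = -np.inf, remaining[0]
        for nm in remaining:  # first name in sorted order wins ties
            sc = score(selected + [nm])
            if sc > add_score:
                add_score, add_name = sc, nm
        selected = selected + [add_name]
        current = add_score
        trace.append(current)
        # floating step: drop any feature (except the newest) that helps
        improved = True
        while improved and len(selected) > 2:
            improved = False
            for nm in sorted(selected[:-1]):
                reduced = [s for s in selected if s != nm]
                sc = score(reduced)
                if sc > current:
                    selected, current = reduced, sc
                    trace.append(current)
                    improved = True
                    break
        if current > best_score:
            best_score, best_set = current, list(selected)
            stall = 0
        else:
            stall += 1
    return best_set, trace


def select_features(
    X: np.ndarray,
    y: Sequence,
    feature_names: Sequence[str],
    *,
    seed: int = 0,
    k_neighbors: int = K_NEIGHBORS,
    evaluator: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> SelectionResult:
    """Run both stages: Relief-F elimination (RI < 0) then SFFS."""
    X = np.asarray(X, dtype=float)
    names = list(feature_names)
    ri = relieff_weights(X, y, k_neighbors=k_neighbors)
    kept = [nm for nm, w in zip(names, ri) if w >= 0]
    if evaluator is None:
        evaluator = make_rf_evaluator(seed)
    keep_idx = [names.index(nm) for nm in kept]
    selected, trace = sffs_select(X[:, keep_idx], y, kept, evaluator)
    return SelectionResult(
        ri=dict(zip(names, ri.tolist())),
        stage1_kept=kept,
        stage2_selected=selected,
        wrapper_scores=trace,
    )
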