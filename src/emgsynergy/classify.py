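"""Class rebalancing, random-forest training and cross-validated F-measure.

Class sizes are equalized to the geometric mean of the original counts:
minority classes are grown with ADASYN (adaptive synthetic oversampling,
density-weighted interpolation between a minority sample and one of its
minority-class neighbours) and majority classes are shrunk by random
sampling with replacement.  Rebalancing is applied to training folds only;
test folds are never resampled.

Performance is summarized per class from the confusion matrix n_ij
(samples of true class i identified as class j):

    P_i  = n_ii / sum_j n_ji          (precision)
    R_i  = n_ii / sum_j n_ij          (recall)
    FM_i = 2 P_i R_i / (P_i + R_i)    (F-measure)

and reported as the mean over stratified folds of the unweighted per-class
mean FM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .errors import DomainError

logger = logging.getLogger(__name__)

N_TREES = 30
N_FOLDS = 10
ADASYN_NEIGHBORS = 5


@dataclass
class ClassificationReport:
    """Cross-validated classification outcome.

    ``confusion`` is summed over the test folds; rows are true classes,
    columns predicted classes, in ``class_labels`` order.  ``mean_fm`` is
    the average over folds of the unweighted per-class mean F-measure.
    """

    confusion: np.ndarray
    class_labels: list
    precision: np.ndarray
    recall: np.ndarray
    f_measure: np.ndarray
    mean_fm: float
    fold_fms: list[float] = field(default_factory=list)
    fold_count: int = N_FOLDS
    feature_set: str = ""
    task: str = ""

    def as_dict(self) -> dict:
        return {
            "task": self.task,
            "feature_set": self.feature_set,
            "fold_count": self.fold_count,
            "class_labels": [str(c) for c in self.class_labels],
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f_measure": self.f_measure.tolist(),
            "fold_fms": self.fold_fms,
            "mean_fm": self.mean_fm,
        }


def geometric_mean_target(counts: np.ndarray) -> int:
    """Per-class target size: rounded geometric mean of the class counts."""
    counts = np.asarray(counts, dtype=float)
    return int(round(float(np.exp(np.mean(np.log(counts))))))


def _adasyn_oversample(
    X: np.ndarray,
    y: np.ndarray,
    cls,
    n_new: int,
    rng: np.random.Generator,
    k: int = ADASYN_NEIGHBORS,
) -> np.ndarray:
    """Generate ``n_new`` synthetic samples for class ``cls`` (ADASYN).

    Each minority sample gets a generation weight proportional to the share
    of other-class samples among its k nearest neighbours in the full data
    (harder regions get more synthetic points); each synthetic point
    interpolates between the sample and a random minority-class neighbour.
    Falls back to duplication when the class is too small for
    neighbourhood estimation (< 6 samples).
    """
    Xc = X[y == cls]
    n_c = Xc.shape[0]
    if n_c < k + 1:
        logger.warning(
            "class %r has %d samples; ADASYN infeasible, duplicating instead",
            cls, n_c,
        )
        idx = rng.integers(0, n_c, size=n_new)
        return Xc[idx]

    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, neigh = nn_all.kneighbors(Xc)
    # drop self-matches (first column after fit on the full set)
    ratios = np.array(
        [np.mean(y[row[1 : k + 1]] != cls) for row in neigh]
    )
    if ratios.sum() == 0:
        weights = np.full(n_c, 1.0 / n_c)
    else:
        weights = ratios / ratios.sum()
    per_sample = rng.multinomial(n_new, weights)

    nn_min = NearestNeighbors(n_neighbors=min(k + 1, n_c)).fit(Xc)
    _, neigh_min = nn_min.kneighbors(Xc)
    out = []
    for i, g in enumerate(per_sample):
        for _ in range(int(g)):
            choices = neigh_min[i][1:]  # exclude self
            z = int(rng.choice(choices))
            lam = rng.random()
            out.append(Xc[i] + lam * (Xc[z] - Xc[i]))
    if not out:
        return np.empty((0, X.shape[1]))
    return np.vstack(out)


def balance_resample(
    X: np.ndarray, y: np.ndarray, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class sizes at the geometric mean of the original counts.

    Classes above the target are undersampled by random sampling with
    replacement; classes below it are topped up with ADASYN synthetic
    samples; classes at the target pass through unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DomainError("rebalancing needs >= 2 classes")
    if np.any(counts == 0):
        raise DomainError("every class must be non-empty")
    target = geometric_mean_target(counts)
    rng = np.random.default_rng(seed)

    xs, ys = [], []
    for cls, cnt in zip(classes, counts):
        Xc = X[y == cls]
        if cnt == target:
            keep = Xc
        elif cnt > target:
            idx = rng.integers(0, cnt, size=target)
            keep = Xc[idx]
        else:
            extra = _adasyn_oversample(X, y, cls, target - cnt, rng)
            keep = np.vstack([Xc, extra])
        xs.append(keep)
        ys.append(np.full(keep.shape[0], cls, dtype=y.dtype))
    return np.vstack(xs), np.concatenate(ys)


def f_measure_report(
    confusion: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class precision, recall and F-measure from a confusion matrix.

    Rows are true classes, columns predicted.  Empty denominators yield 0
    (an empty true class is flagged with a warning).
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise DomainError("confusion matrix must be square")
    diag = np.diag(conf)
    pred_totals = conf.sum(axis=0)
    true_totals = conf.sum(axis=1)
    if np.any(true_totals == 0):
        logger.warning("empty true class in confusion matrix; recall reported as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_totals > 0, diag / pred_totals, 0.0)
        recall = np.where(true_totals > 0, diag / true_totals, 0.0)
        s = precision + recall
        fm = np.where(s > 0, 2 * precision * recall / np.where(s > 0, s, 1.0), 0.0)
    return precision, recall, fm


def cross_validated_fm(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_trees: int = N_TREES,
    n_folds: int = N_FOLDS,
    seed: int = 0,
    rebalance: bool = True,
    feature_set: str = "",
    task: str = "",
) -> ClassificationReport:
    """Stratified k-fold evaluation of a random forest with rebalanced training.

    Per fold: the training portion only is rebalanced, a ``n_trees``-tree
    random forest (bootstrap, sqrt(p) candidate features per split,
    unlimited depth, majority vote) is trained, and the untouched test fold
    predicted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    _, counts = np.unique(y, return_counts=True)
    if np.any(counts < n_folds):
        raise DomainError(
            f"smallest class has {counts.min()} samples; "
            f"stratified {n_folds}-fold needs >= {n_folds}"
        )
    idx = {c: i for i, c in enumerate(classes)}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    total_conf = np.zeros((classes.size, classes.size), dtype=int)
    fold_fms: list[float] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X[tr], y[tr]
        if rebalance:
            X_tr, y_tr = balance_resample(X_tr, y_tr, seed=seed + fold)
        assert len(te) == len(set(te)) and set(te).isdisjoint(tr)  # leak freedom
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            bootstrap=True,
            random_state=seed + fold,
        )
        clf.fit(X_tr, y_tr)
        pred = clf.predict(X[te])
        conf = np.zeros_like(total_conf)
        for t, p in zip(y[te], pred):
            conf[idx[t], idx[p]] += 1
        total_conf += conf
        _, _, fm = f_measure_report(conf)
        fold_fms.append(float(np.mean(fm)))

    precision, recall, fm = f_measure_report(total_conf)
    return ClassificationReport(
        confusion=total_conf,
        class_labels=classes.tolist(),
        precision=precision,
        recall=recall,
        f_measure=fm,
        mean_fm=float(np.mean(fold_fms)),
        fold_fms=fold_fms,
        fold_count=n_folds,
        feature_set=feature_set,
        task=task,
    )
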