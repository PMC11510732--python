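"""KNN variants, repeated stratified cross-validation and confusion metrics.

Three named presets follow a common taxonomy of nearest-neighbour
configurations:

* FKNN ("fine"):     k = 1,   Euclidean distance, uniform votes
* WKNN ("weighted"): k = 100, Euclidean distance, votes weighted 1/d^2
* CKNN ("cubic"):    k = 10,  Minkowski order-3 distance, uniform votes

The voting contracts are explicit: uniform ties resolve to the label of the
smallest-index neighbour among the k nearest; under squared-inverse weighting
a zero-distance neighbour decides outright.  The evaluation protocol is
stratified 10-fold cross-validation with a fresh seeded shuffle per repeat;
fold confusion matrices are aggregated per repeat and the summary metrics are
means over repeats.  Schizophrenia is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold

from .errors import InputError, ParameterError, SchemeError
from .selection import AnovaKBest, LabeledFeatureMatrix

POSITIVE_CLASS = "schizophrenia"


@dataclass(frozen=True)
class KNNSpec:
    """A nearest-neighbour configuration."""

    k: int = 1
    metric: str = "euclidean"       # euclidean | minkowski_p3
    weighting: str = "uniform"      # uniform | squared_inverse

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.metric not in ("euclidean", "minkowski_p3"):
            raise ParameterError(f"unknown metric {self.metric!r}")
        if self.weighting not in ("uniform", "squared_inverse"):
            raise ParameterError(f"unknown weighting {self.weighting!r}")


PRESETS = {
    "fknn": KNNSpec(k=1, metric="euclidean", weighting="uniform"),
    "wknn": KNNSpec(k=100, metric="euclidean", weighting="squared_inverse"),
    "cknn": KNNSpec(k=10, metric="minkowski_p3", weighting="uniform"),
}


def get_spec(name_or_spec) -> KNNSpec:
    if isinstance(name_or_spec, KNNSpec):
        return name_or_spec
    try:
        return PRESETS[str(name_or_spec).lower()]
    except KeyError:
        raise ParameterError(
            f"unknown KNN preset {name_or_spec!r}; choose from {sorted(PRESETS)}"
        ) from None


def _distances(train_X: np.ndarray, query: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return cdist(query, train_X, metric="euclidean")
    return cdist(query, train_X, metric="minkowski", p=3)


def _vote(labels: np.ndarray, dists: np.ndarray, spec: KNNSpec):
    """Vote among the k nearest; ``labels``/``dists`` are already the k
    nearest in ascending distance order (original index order on ties)."""
    if spec.weighting == "uniform":
        uniq, counts = np.unique(labels, return_counts=True)
        winners = uniq[counts == counts.max()]
        if winners.size == 1:
            return winners[0]
        # tie: the smallest-index (nearest) neighbour with a winning label
        for lab in labels:
            if lab in winners:
                return lab
    # squared-inverse weighting
    zero = dists == 0
    if np.any(zero):
        return labels[np.argmax(zero)]
    weights = 1.0 / dists ** 2
    uniq = np.unique(labels)
    sums = np.array([weights[labels == u].sum() for u in uniq])
    winners = uniq[sums == sums.max()]
    if winners.size == 1:
        return winners[0]
    for lab in labels:
        if lab in winners:
            return lab
    raise AssertionError("unreachable")


def knn_predict(train_X, train_y, spec: KNNSpec, query) -> np.ndarray:
    """Classify query rows by k-nearest-neighbour voting.

    ``query`` may be one vector or a matrix of rows; k is clipped (with a
    warning) when the training set is smaller than k.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.ndim != 2 or train_X.shape[0] == 0:
        raise InputError("training set must be a non-empty 2-D matrix")
    query = np.atleast_2d(np.asarray(query, dtype=float))
    k = spec.k
    if k > train_X.shape[0]:
        import warnings

        warnings.warn(
            f"k={k} exceeds training size {train_X.shape[0]}; clipping"
        )
        k = train_X.shape[0]
    d = _distances(train_X, query, spec.metric)
    # stable argsort so equal distances keep original (smallest) index first
    nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
    out = np.empty(query.shape[0], dtype=train_y.dtype)
    for i in range(query.shape[0]):
        idx = nearest[i]
        out[i] = _vote(train_y[idx], d[i, idx], spec)
    return out


class KnnVariant(ClassifierMixin, BaseEstimator):
    """scikit-learn-style wrapper around the explicit KNN voting rules.

    ``spec`` may be a preset name ('fknn', 'wknn', 'cknn') or a KNNSpec.
    """

    def __init__(self, spec="fknn"):
        self.spec = spec

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise InputError("empty training set")
        self.spec_ = get_spec(self.spec)
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return knn_predict(self.X_, self.y_, self.spec_, X)


# ---------------------------------------------------------------------------
# Confusion matrices and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Binary confusion counts with schizophrenia as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp, tn=self.tn + other.tn,
            fp=self.fp + other.fp, fn=self.fn + other.fn,
        )


def confusion_from_predictions(
    y_true, y_pred, positive=POSITIVE_CLASS
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, sensitivity (TPR on the disease class), specificity (TNR),
    precision.  A zero denominator yields ``nan`` as the undefined sentinel."""
    if cm.total == 0:
        raise InputError("empty confusion matrix")

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "precision": ratio(cm.tp, cm.tp + cm.fp),
    }


# ---------------------------------------------------------------------------
# Repeated stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-repeat aggregated confusions plus averaged summary metrics."""

    per_repeat: list[ConfusionMatrix]
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    accuracy_sd: float
    folds: int
    repeats: int
    seed: int
    selection: str
    top_k: int | None
    spec: KNNSpec = field(default=None)

    @property
    def per_repeat_accuracy(self) -> list[float]:
        return [confusion_metrics(cm)["accuracy"] for cm in self.per_repeat]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy_sd": self.accuracy_sd,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "selection": self.selection,
            "top_k": self.top_k,
            "knn": {
                "k": self.spec.k,
                "metric": self.spec.metric,
                "weighting": self.spec.weighting,
            } if self.spec else None,
            "per_repeat": [
                {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
                for c in self.per_repeat
            ],
        }


def crossvalidate(
    matrix: LabeledFeatureMatrix,
    spec="fknn",
    folds: int = 10,
    repeats: int = 20,
    seed: int = 0,
    selection: str = "fold",
    top_k: int | None = 10,
    positive=POSITIVE_CLASS,
    subject_cv: bool = False,
) -> CVReport:
    """Repeated stratified k-fold evaluation of a KNN variant.

    ``selection='fold'`` re-ranks features by ANOVA weight inside each
    training fold (no selection leakage); ``'global'`` ranks once on the full
    table, reproducing the workflow where ranking precedes cross-validation.
    ``subject_cv=True`` keeps all epochs of a subject in the same fold
    (grouped CV), the leakage-free alternative to epoch-level folding.
    Deterministic for a fixed ``seed``: repeat r shuffles with seed + r.
    """
    spec = get_spec(spec)
    if selection not in ("fold", "global"):
        raise ParameterError(f"unknown selection scope {selection!r}")
    X, y = matrix.X, matrix.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise SchemeError(
            f"smallest class has {counts.min()} observations; cannot make {folds} folds"
        )
    if top_k is not None and not 1 <= top_k <= X.shape[1]:
        raise ParameterError(f"top_k={top_k} out of range for {X.shape[1]} features")
    if positive not in classes:
        # fall back to the lexicographically larger class so binary metrics
        # remain defined on e.g. {0, 1} labelled data
        positive = classes[-1]
    if subject_cv and matrix.subject_ids is None:
        raise SchemeError("subject_cv requires subject_ids on the feature matrix")

    if selection == "global" and top_k is not None:
        sel = AnovaKBest(k=top_k).fit(X, y)
        X_global = sel.transform(X)
    else:
        X_global = None

    per_repeat: list[ConfusionMatrix] = []
    for r in range(repeats):
        if subject_cv:
            splitter = StratifiedGroupKFold(
                n_splits=folds, shuffle=True, random_state=seed + r
            )
            splits = splitter.split(X, y, groups=matrix.subject_ids)
        else:
            splitter = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=seed + r
            )
            splits = splitter.split(X, y)
        agg = ConfusionMatrix()
        for train_idx, test_idx in splits:
            if X_global is not None:
                Xtr, Xte = X_global[train_idx], X_global[test_idx]
            elif top_k is not None:
                sel = AnovaKBest(k=top_k).fit(X[train_idx], y[train_idx])
                Xtr, Xte = sel.transform(X[train_idx]), sel.transform(X[test_idx])
            else:
                Xtr, Xte = X[train_idx], X[test_idx]
            pred = knn_predict(Xtr, y[train_idx], spec, Xte)
            agg = agg + confusion_from_predictions(y[test_idx], pred, positive)
        per_repeat.append(agg)

    metrics = [confusion_metrics(cm) for cm in per_repeat]
    acc = np.array([m["accuracy"] for m in metrics])
    return CVReport(
        per_repeat=per_repeat,
        accuracy=float(acc.mean()),
        sensitivity=float(np.mean([m["sensitivity"] for m in metrics])),
        specificity=float(np.mean([m["specificity"] for m in metrics])),
        precision=float(np.mean([m["precision"] for m in metrics])),
        accuracy_sd=float(acc.std(ddof=1)) if repeats > 1 else 0.0,
        folds=folds,
        repeats=repeats,
        seed=seed,
        selection="subject" if subject_cv else selection,
        top_k=top_k,
        spec=spec,
    )
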