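"""One-way ANOVA F-weights for univariate feature ranking.

Each feature column is scored by the F statistic of a one-way analysis of
variance across class labels: the total sum of squares is split into the
between-class part SSR and the within-class part SSE, and

    F = (SSR / (k - 1)) / (SSE / (n - k))

for k classes and n observations.  A perfectly separating feature (SSE = 0
with SSR > 0) receives a +inf sentinel so it always outranks finite weights;
a feature with no between-class variation scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InputError, ParameterError


@dataclass
class LabeledFeatureMatrix:
    """Observations x features with per-row class labels."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise InputError("feature matrix must be 2-D")
        if len(self.labels) != self.X.shape[0]:
            raise InputError("one label per row required")
        if not self.feature_names:
            self.feature_names = tuple(f"f{j}" for j in range(self.X.shape[1]))
        if len(self.feature_names) != self.X.shape[1]:
            raise InputError("one name per feature column required")
        if not np.all(np.isfinite(self.X)):
            raise InputError("feature matrix contains non-finite values")
        # class layout (>= 2 classes, >= 2 observations each) is enforced by
        # the consumers that need it (ANOVA ranking, cross-validation), so a
        # single-class table can still hold extracted features.

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["label"] = self.labels
        if self.subject_ids is not None:
            df["subject_id"] = self.subject_ids
        return df


@dataclass
class RankedFeatures:
    """F-weights with the descending stable ordering they induce."""

    weights: np.ndarray
    order: np.ndarray
    selected: np.ndarray
    feature_names: tuple[str, ...]

    def report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": [self.feature_names[i] for i in self.order],
            "weight": self.weights[self.order],
            "rank": np.arange(1, len(self.order) + 1),
        })


def anova_weight(column: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F statistic of one feature column against class labels."""
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    classes, inverse, counts = np.unique(
        labels, return_inverse=True, return_counts=True
    )
    k = classes.size
    n = column.size
    if k < 2:
        raise InputError("need at least 2 classes")
    if counts.min() < 2:
        raise InputError("every class needs at least 2 observations")
    grand = column.mean()
    group_sums = np.bincount(inverse, weights=column, minlength=k)
    group_means = group_sums / counts
    ssr = float(np.sum(counts * (group_means - grand) ** 2))
    sse = float(np.sum((column - group_means[inverse]) ** 2))
    if ssr == 0.0:
        return 0.0
    if sse == 0.0:
        return float("inf")
    return (ssr / (k - 1)) / (sse / (n - k))


def anova_weights(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.array([anova_weight(X[:, j], labels) for j in range(X.shape[1])])


def rank_and_select(matrix: LabeledFeatureMatrix, k: int = 10) -> RankedFeatures:
    """Score every column, sort descending (stable: ties keep the lower
    index), and retain the top ``k``."""
    if not 1 <= k <= matrix.n_features:
        raise ParameterError(
            f"k={k} out of range for {matrix.n_features} features"
        )
    weights = anova_weights(matrix.X, matrix.labels)
    order = np.argsort(-weights, kind="stable")
    return RankedFeatures(
        weights=weights,
        order=order,
        selected=order[:k],
        feature_names=matrix.feature_names,
    )


class AnovaKBest(TransformerMixin, BaseEstimator):
    """Select the k features with the largest one-way ANOVA F-weights.

    Fitted attributes: ``weights_`` (F per column), ``order_`` (descending,
    ties to the lower index), ``selected_`` (top-k column indices).
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not 1 <= self.k <= X.shape[1]:
            raise ParameterError(f"k={self.k} out of range for {X.shape[1]} features")
        self.weights_ = anova_weights(X, y)
        self.order_ = np.argsort(-self.weights_, kind="stable")
        self.selected_ = self.order_[: self.k]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InputError("feature count changed between fit and transform")
        return X[:, self.selected_]

    def get_support(self) -> np.ndarray:
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask
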