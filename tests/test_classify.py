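"""KNN voting rules, repeated stratified CV, confusion metrics."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from aleewr.classify import (
    PRESETS,
    ConfusionMatrix,
    KnnVariant,
    KNNSpec,
    confusion_from_predictions,
    confusion_metrics,
    crossvalidate,
    knn_predict,
)
from aleewr.errors import InputError, ParameterError, SchemeError
from aleewr.selection import LabeledFeatureMatrix


def blob_matrix(rng, n_per_class=60, n_features=5, separation=10.0):
    X = np.vstack([
        rng.standard_normal((n_per_class, n_features)),
        rng.standard_normal((n_per_class, n_features)) + separation,
    ])
    y = np.array(["healthy"] * n_per_class + ["schizophrenia"] * n_per_class)
    return LabeledFeatureMatrix(X=X, labels=y, feature_names=())


class TestPresets:
    def test_named_variants(self):
        assert PRESETS["fknn"] == KNNSpec(1, "euclidean", "uniform")
        assert PRESETS["wknn"] == KNNSpec(100, "euclidean", "squared_inverse")
        assert PRESETS["cknn"] == KNNSpec(10, "minkowski_p3", "uniform")

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            KNNSpec(k=0)
        with pytest.raises(ParameterError):
            KNNSpec(metric="manhattan")


class TestKnnPredict:
    def test_single_training_point_clips_k(self):
        with pytest.warns(UserWarning, match="clipping"):
            out = knn_predict(np.array([[0.0]]), np.array(["h"]),
                              KNNSpec(k=5), np.array([[3.0]]))
        assert out[0] == "h"

    def test_resubstitution_with_k1_is_exact(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.choice(["h", "s"], size=30)
        pred = knn_predict(X, y, PRESETS["fknn"], X)
        np.testing.assert_array_equal(pred, y)

    def test_squared_inverse_hand_case(self):
        """Weights 1/d^2 for query 2 against points 0, 1, 10:
        h gets 1/4 + 1 = 1.25, s gets 1/64 -> h wins."""
        X = np.array([[0.0], [1.0], [10.0]])
        y = np.array(["h", "h", "s"])
        spec = KNNSpec(k=3, weighting="squared_inverse")
        assert knn_predict(X, y, spec, np.array([[2.0]]))[0] == "h"

    def test_zero_distance_neighbour_decides(self):
        X = np.array([[1.0], [2.0]])
        y = np.array(["h", "s"])
        spec = KNNSpec(k=2, weighting="squared_inverse")
        assert knn_predict(X, y, spec, np.array([[2.0]]))[0] == "s"

    def test_uniform_tie_resolves_to_nearest(self):
        # k=2, one vote each: the nearer neighbour's label wins
        X = np.array([[1.0], [4.0]])
        y = np.array(["s", "h"])
        spec = KNNSpec(k=2)
        assert knn_predict(X, y, spec, np.array([[2.0]]))[0] == "s"

    def test_matches_sklearn_where_contracts_agree(self, rng):
        """Independent oracle: with odd k and uniform voting there are no
        ties, so sklearn's KNeighborsClassifier must agree exactly."""
        Xtr = rng.standard_normal((50, 3))
        ytr = rng.choice(["h", "s"], size=50)
        Xte = rng.standard_normal((20, 3))
        for k, metric, p in [(1, "euclidean", 2), (3, "euclidean", 2),
                             (5, "minkowski_p3", 3)]:
            spec = KNNSpec(k=k, metric=metric)
            skl = KNeighborsClassifier(
                n_neighbors=k, metric="minkowski", p=p).fit(Xtr, ytr)
            np.testing.assert_array_equal(
                knn_predict(Xtr, ytr, spec, Xte), skl.predict(Xte))

    def test_empty_training_set(self):
        with pytest.raises(InputError):
            knn_predict(np.empty((0, 2)), np.array([]), PRESETS["fknn"],
                        np.array([[1.0, 2.0]]))

    def test_estimator_wrapper(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.array(["h"] * 10 + ["s"] * 10)
        est = KnnVariant(spec="fknn").fit(X, y)
        np.testing.assert_array_equal(est.predict(X), y)
        assert set(est.classes_) == {"h", "s"}


class TestConfusionMetrics:
    def test_printed_fknn_row_arithmetic(self):
        cm = ConfusionMatrix(tp=500, tn=502, fp=2, fn=4)
        m = confusion_metrics(cm)
        assert round(100 * m["accuracy"], 2) == 99.40
        assert round(100 * m["sensitivity"], 2) == 99.21
        assert round(100 * m["specificity"], 2) == 99.60

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(tp=1, tn=1, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_sentinel(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(m["sensitivity"])

    def test_confusion_from_predictions_orientation(self):
        y_true = np.array(["schizophrenia", "schizophrenia", "healthy"])
        y_pred = np.array(["schizophrenia", "healthy", "healthy"])
        cm = confusion_from_predictions(y_true, y_pred)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 0)


class TestCrossvalidate:
    def test_separable_blobs_are_perfect(self, rng):
        matrix = blob_matrix(rng)
        report = crossvalidate(matrix, spec="fknn", folds=10, repeats=3,
                               seed=0, top_k=None)
        assert report.accuracy == 1.0

    def test_shuffled_labels_sit_at_chance(self, rng):
        matrix = blob_matrix(rng, separation=0.0)
        report = crossvalidate(matrix, spec="fknn", folds=10, repeats=20,
                               seed=1, top_k=None)
        se = np.sqrt(0.25 / matrix.X.shape[0])
        assert abs(report.accuracy - 0.5) < 3 * se + 0.05

    def test_fold_sizes_partition_rows(self, rng):
        matrix = blob_matrix(rng, n_per_class=25)
        report = crossvalidate(matrix, spec="fknn", folds=10, repeats=2,
                               seed=0, top_k=None)
        for cm in report.per_repeat:
            assert cm.total == 50
        # stratified folds differ in size by at most 1
        from sklearn.model_selection import StratifiedKFold

        sizes = [len(te) for _, te in StratifiedKFold(
            n_splits=10, shuffle=True, random_state=0).split(
                matrix.X, matrix.labels)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_for_fixed_seed(self, rng):
        matrix = blob_matrix(rng, separation=1.0)
        r1 = crossvalidate(matrix, spec="wknn", folds=5, repeats=2, seed=9,
                           top_k=3)
        r2 = crossvalidate(matrix, spec="wknn", folds=5, repeats=2, seed=9,
                           top_k=3)
        assert r1.to_dict() == r2.to_dict()

    def test_class_smaller_than_folds_rejected(self, rng):
        matrix = blob_matrix(rng, n_per_class=5)
        with pytest.raises(SchemeError):
            crossvalidate(matrix, folds=10, repeats=1, seed=0, top_k=None)

    def test_global_vs_fold_selection_scopes_run(self, rng):
        matrix = blob_matrix(rng, separation=2.0)
        for scope in ("fold", "global"):
            rep = crossvalidate(matrix, spec="fknn", folds=5, repeats=1,
                                seed=0, selection=scope, top_k=2)
            assert 0.9 <= rep.accuracy <= 1.0

    def test_subject_cv_requires_and_uses_groups(self, rng):
        matrix = blob_matrix(rng)
        with pytest.raises(SchemeError):
            crossvalidate(matrix, folds=5, repeats=1, seed=0, top_k=None,
                          subject_cv=True)
        matrix.subject_ids = np.array(
            [f"subj{i // 12}" for i in range(matrix.X.shape[0])])
        rep = crossvalidate(matrix, folds=5, repeats=1, seed=0, top_k=None,
                            subject_cv=True)
        assert rep.selection == "subject"
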