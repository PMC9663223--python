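"""SVM training, margin geometry, and the repeated cross-validation scheme."""

import numpy as np
import pandas as pd
import pytest

from fnirs_upb.classify import cross_validate, per_subject_report, train_svm
from fnirs_upb.features import FeatureMatrix, fit_minmax


def feature_matrix(X, labels):
    return FeatureMatrix(
        X=np.asarray(X, float),
        labels=np.asarray(labels),
        meta=pd.DataFrame({"row": range(len(labels))}),
        feature_names=tuple(f"f{i}" for i in range(np.asarray(X).shape[1])),
    )


def two_clouds(rng, n=40, sep=6.0, d=2):
    X = np.vstack(
        [rng.standard_normal((n, d)), rng.standard_normal((n, d)) + sep]
    )
    labels = np.array(["Task2"] * n + ["Task1"] * n)
    return feature_matrix(X, labels)


class TestTrainSVM:
    def test_separable_clouds_perfect_training_accuracy(self, rng):
        fm = two_clouds(rng)
        y = (fm.labels == "Task1").astype(int)
        model = train_svm(fm.X, y)
        assert np.mean(model.predict(fm.X) == y) == 1.0
        assert model.margin > 0

    def test_closed_form_max_margin_hyperplane(self):
        """Points (0,0)- and (2,0)+: hyperplane x=1, w=(1,0), margin 2/||w||=2."""
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array([0, 1])
        model = train_svm(X, y, C=1.0)
        np.testing.assert_allclose(model.w, [1.0, 0.0], atol=1e-6)
        assert model.b == pytest.approx(-1.0, abs=1e-6)
        assert model.margin == pytest.approx(2.0, abs=1e-6)

    def test_margin_equals_two_over_weight_norm(self, rng):
        fm = two_clouds(rng, sep=8.0, d=5)
        y = (fm.labels == "Task1").astype(int)
        model = train_svm(fm.X, y)
        assert model.margin == pytest.approx(2.0 / np.linalg.norm(model.w), rel=1e-12)
        # support vectors sit at or outside the unit-score hyperplanes
        sv_scores = model.decision_function(model.estimator.support_vectors_)
        assert np.all(np.abs(sv_scores) >= 1 - 1e-3)  # within solver tolerance

    def test_contradictory_labels_do_not_crash(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0]])
        model = train_svm(X, np.array([0, 1]))
        acc = np.mean(model.predict(X) == np.array([0, 1]))
        assert acc <= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_svm(np.zeros((4, 2)), np.zeros(4))

    def test_rbf_kernel_has_no_weight_vector(self, rng):
        fm = two_clouds(rng)
        y = (fm.labels == "Task1").astype(int)
        model = train_svm(fm.X, y, kernel="rbf")
        with pytest.raises(AttributeError):
            _ = model.w


class TestCrossValidate:
    def test_separated_classes_accuracy_one_sem_zero(self, rng):
        cv = cross_validate(two_clouds(rng, sep=10.0), seed=0)
        assert cv.mean == 1.0
        assert cv.sd == 0.0 and cv.sem == 0.0
        assert cv.n_iterations == 30

    def test_fixed_seed_reproducible(self, rng):
        fm = two_clouds(rng, sep=1.0)
        cv1 = cross_validate(fm, seed=5)
        cv2 = cross_validate(fm, seed=5)
        np.testing.assert_array_equal(cv1.accuracies, cv2.accuracies)
        np.testing.assert_array_equal(cv1.scores, cv2.scores)

    def test_shuffled_labels_near_chance(self):
        """Permutation null: mean accuracy within 3 SEM of 0.5 over 50 runs."""
        rng = np.random.default_rng(17)
        means = []
        for k in range(50):
            X = rng.standard_normal((150, 6))
            labels = np.array(["Task1"] * 75 + ["Task2"] * 75)
            rng.shuffle(labels)
            means.append(cross_validate(feature_matrix(X, labels), seed=k).mean)
        means = np.array(means)
        sem = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 0.5) < 3 * sem

    def test_default_synthetic_subject_reaches_090(self, default_subject):
        *_, fm = default_subject
        cv = cross_validate(fm, seed=1)
        assert cv.mean >= 0.90

    def test_small_class_suggests_channel_trial_unit(self, rng):
        fm = feature_matrix(rng.standard_normal((10, 6)), ["Task1"] * 5 + ["Task2"] * 5)
        with pytest.raises(ValueError, match="channel"):
            cross_validate(fm)

    def test_kfold_scheme_runs_30_iterations(self, rng):
        cv = cross_validate(two_clouds(rng), scheme="kfold10", n_repeats=30, seed=0)
        assert cv.n_iterations == 30
        assert cv.scheme == "kfold10"

    def test_sem_definition(self, rng):
        cv = cross_validate(two_clouds(rng, sep=1.0), seed=3)
        assert cv.sem == pytest.approx(
            np.std(cv.accuracies, ddof=1) / np.sqrt(30), rel=1e-12
        )


class TestAntiLeakage:
    def test_training_contamination_measurably_inflates_near_null(self):
        """Fitting the SVM with test rows included inflates accuracy; the
        cross-validation path (rescaler and model fitted on train folds only)
        stays near chance on near-null data."""
        rng = np.random.default_rng(4)
        clean, contaminated = [], []
        for k in range(30):
            X = rng.standard_normal((80, 6))
            X[40:, 0] += 0.3  # near-null contrast
            labels = np.array(["Task2"] * 40 + ["Task1"] * 40)
            fm = feature_matrix(X, labels)
            clean.append(cross_validate(fm, n_repeats=10, seed=k).mean)
            y = (labels == "Task1").astype(int)
            scaler = fit_minmax(X)
            Xs = scaler.transform(X)
            model = train_svm(Xs, y)
            contaminated.append(float(np.mean(model.predict(Xs) == y)))
        inflation = np.mean(contaminated) - np.mean(clean)
        assert inflation > 0.05

    def test_global_rescale_mode_is_label_blind(self, rng):
        """The pooled (leaky) rescale is an affine map and cannot create class
        separation on its own: both modes stay near chance on pure noise."""
        X = rng.standard_normal((100, 6))
        labels = np.array(["Task1"] * 50 + ["Task2"] * 50)
        fm = feature_matrix(X, labels)
        clean = cross_validate(fm, n_repeats=20, seed=0).mean
        leaky = cross_validate(fm, n_repeats=20, seed=0, leak_rescale=True).mean
        assert abs(clean - 0.5) < 0.2 and abs(leaky - 0.5) < 0.2


class TestPerSubjectReport:
    def test_grand_mean_of_two_subjects(self, rng):
        fm = two_clouds(rng, sep=10.0)
        cv = cross_validate(fm, seed=0)
        report = per_subject_report({1: cv, 2: cv})
        grand = report[report.subject == "A"].iloc[0]
        assert grand.accuracy == pytest.approx(1.0)

    def test_single_subject_grand_equals_subject(self, rng):
        cv = cross_validate(two_clouds(rng, sep=1.0), seed=0)
        report = per_subject_report({7: cv})
        assert report.accuracy.iloc[0] == pytest.approx(cv.mean)
        assert report[report.subject == "A"].accuracy.iloc[0] == pytest.approx(cv.mean)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            per_subject_report({})
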