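"""Per-subject SVM classification of promotion (UPB) vs control trials.

The classifier is a maximum-margin SVM (linear kernel by default, matching the
hyperplane d(x) = Wᵀx + b whose margin 2/‖W‖ the training maximizes; RBF by
config).  Evaluation follows the study's repeated scheme: 30 stratified
shuffled 80%/20% train/test splits ("8 train sets and 2 test sets" of 10
folds, tested 30 times), with the min-max rescaler re-fitted on each split's
training rows so no test information leaks into scaling.  A classic 10-fold
x 3-repeat mode is available as the alternative reading of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .features import FeatureMatrix, apply_minmax, fit_minmax

POSITIVE_LABEL = "Task1"  # the promotion condition elicits UPB → positive class


@dataclass
class SVMModel:
    """Fitted SVM with margin accessors for the linear kernel."""

    estimator: SVC
    kernel: str

    @property
    def w(self) -> np.ndarray:
        if self.kernel != "linear":
            raise AttributeError("weight vector only defined for the linear kernel")
        return self.estimator.coef_.ravel()

    @property
    def b(self) -> float:
        if self.kernel != "linear":
            raise AttributeError("offset only defined for the linear kernel")
        return float(self.estimator.intercept_[0])

    @property
    def margin(self) -> float:
        """Maximum margin 2/‖w‖ between the support-vector hyperplanes."""
        return 2.0 / float(np.linalg.norm(self.w))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    max_iter: int = -1,
) -> SVMModel:
    """Fit a maximum-margin SVM; requires both classes present."""
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    est = SVC(kernel=kernel, C=C, max_iter=max_iter)
    est.fit(X, y)
    return SVMModel(estimator=est, kernel=kernel)


@dataclass
class CVResult:
    """Repeated-split accuracies plus pooled out-of-fold decision scores."""

    accuracies: np.ndarray  # fraction correct per iteration
    scores: np.ndarray  # pooled decision values over all test folds
    score_labels: np.ndarray  # 1 = UPB (Task1), 0 = non-UPB, aligned with scores
    seed: int
    scheme: str

    @property
    def n_iterations(self) -> int:
        return self.accuracies.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if self.n_iterations > 1 else 0.0

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n_iterations)


def cross_validate(
    m: FeatureMatrix,
    scheme: str = "shuffled80",
    n_repeats: int = 30,
    seed: int = 0,
    kernel: str = "linear",
    C: float = 1.0,
    leak_rescale: bool = False,
) -> CVResult:
    """Repeated cross-validation with per-split min-max rescaling.

    ``scheme="shuffled80"`` (default): ``n_repeats`` independent stratified
    80/20 shuffled splits.  ``scheme="kfold10"``: stratified 10-fold repeated
    ``n_repeats // 10`` times.  ``leak_rescale=True`` fits the rescaler on the
    full matrix instead of the training rows only — a deliberately leaky mode
    kept for demonstrating the inflation it causes, never for analysis.
    """
    y = (m.labels == POSITIVE_LABEL).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("cross-validation needs both conditions present")
    if counts.min() < 10:
        raise ValueError(
            f"smallest class has {counts.min()} samples (<10); use the per-(channel,trial) "
            "sample unit so each condition contributes channels x trials rows"
        )
    if scheme == "shuffled80":
        splitter = StratifiedShuffleSplit(
            n_splits=n_repeats, test_size=0.2, random_state=seed
        )
    elif scheme == "kfold10":
        splitter = RepeatedStratifiedKFold(
            n_splits=10, n_repeats=max(1, n_repeats // 10), random_state=seed
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    accuracies, all_scores, all_labels = [], [], []
    for train_idx, test_idx in splitter.split(m.X, y):
        fit_rows = None if leak_rescale else train_idx
        scaler = fit_minmax(m.X, fit_rows)
        Xs = scaler.transform(m.X)
        model = train_svm(Xs[train_idx], y[train_idx], kernel=kernel, C=C)
        pred = model.predict(Xs[test_idx])
        accuracies.append(float(np.mean(pred == y[test_idx])))
        all_scores.append(model.decision_function(Xs[test_idx]))
        all_labels.append(y[test_idx])
    return CVResult(
        accuracies=np.asarray(accuracies),
        scores=np.concatenate(all_scores),
        score_labels=np.concatenate(all_labels),
        seed=seed,
        scheme=scheme,
    )


def per_subject_report(results: dict[int, CVResult]) -> pd.DataFrame:
    """Per-subject mean ± SEM accuracies plus the grand-average row.

    The grand row ("A") reports the mean of the per-subject means and the SEM
    across subjects.
    """
    if not results:
        raise ValueError("no subjects")
    rows = [
        {"subject": str(s), "accuracy": r.mean, "sem": r.sem}
        for s, r in sorted(results.items())
    ]
    means = np.array([r["accuracy"] for r in rows])
    grand_sem = (
        float(np.std(means, ddof=1) / np.sqrt(means.size)) if means.size > 1 else 0.0
    )
    rows.append({"subject": "A", "accuracy": float(np.mean(means)), "sem": grand_sem})
    return pd.DataFrame(rows)
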