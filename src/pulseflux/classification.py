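"""Vessel-state classification with a one-vs-all ECOC linear SVM.

Each row of the feature matrix is one 10-s window (four PPG morphology
features, optionally joined with the LDF DC mean flux on matching class and
window); models are trained separately per PPG wavelength.  Three binary
soft-margin linear SVMs are combined through the one-vs-all coding matrix

    healthy       (+1, -1, -1)
    intermediate  (-1, +1, -1)
    unhealthy     (-1, -1, +1)

and predictions decode to the codeword with the smallest aggregate hinge
loss over the binary decision values (ties broken by class order).
Columns are standardized with training-set statistics only (and per fold
within cross-validation).  Evaluation follows a stratified random 70/30
holdout for the confusion matrix and per-class precision/recall/F1, plus
stratified 5-fold cross-validated accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core_io import PHANTOM_CLASSES
from .ppg_features import PPG_FEATURE_NAMES

__all__ = [
    "FeatureMatrix",
    "ClassifierReport",
    "EcocLinearSvm",
    "build_matrix",
    "train_ecoc_svm",
    "report_from_confusion",
    "evaluate",
]

#: One-vs-all coding matrix, rows ordered like PHANTOM_CLASSES.
CODING_MATRIX = np.array(
    [
        [+1, -1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
    ],
    dtype=float,
)


@dataclass
class FeatureMatrix:
    """Windowed feature rows with class labels for one (BMF, wavelength) model."""

    X: pd.DataFrame
    y: np.ndarray
    bmf: str
    wavelength_nm: int
    multimodal: bool

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        present = set(np.unique(self.y))
        missing = [c for c in PHANTOM_CLASSES if c not in present]
        if missing:
            raise ValueError(f"labels must cover all three classes; missing {missing}")


def build_matrix(
    ppg_features: pd.DataFrame,
    ldf_features: pd.DataFrame | None,
    bmf: str,
    wavelength_nm: int,
    multimodal: bool = False,
) -> FeatureMatrix:
    """Assemble the window-level matrix for one wavelength and BMF regime.

    The multimodal variant appends the LDF DC mean flux joined on
    (phantom_class, window_index); windows lacking a join partner are
    dropped.  72 rows (3 classes x 24 windows) at default conditions.
    """
    sub = ppg_features[
        (ppg_features["bmf"] == bmf) & (ppg_features["wavelength_nm"] == wavelength_nm)
    ].copy()
    if sub.empty:
        raise ValueError(f"no PPG feature rows for bmf={bmf!r}, wavelength={wavelength_nm}")
    columns = list(PPG_FEATURE_NAMES)
    if multimodal:
        if ldf_features is None:
            raise ValueError("multimodal matrix requested but no LDF feature table given")
        flux = ldf_features[ldf_features["bmf"] == bmf][
            ["phantom_class", "window_index", "dc_mean_flux"]
        ]
        before = len(sub)
        sub = sub.merge(flux, on=["phantom_class", "window_index"], how="inner")
        if sub.empty:
            raise ValueError("PPG/LDF join produced no rows")
        if len(sub) < before:
            import logging

            logging.getLogger(__name__).warning(
                "dropped %d window rows lacking an LDF join partner", before - len(sub)
            )
        columns.append("dc_mean_flux")
    sub = sub.dropna(subset=columns)
    return FeatureMatrix(
        X=sub[columns].reset_index(drop=True),
        y=sub["phantom_class"].to_numpy(),
        bmf=bmf,
        wavelength_nm=wavelength_nm,
        multimodal=multimodal,
    )


class EcocLinearSvm:
    """One-vs-all ECOC ensemble of binary linear soft-margin SVMs.

    Deterministic given the data: the binary learners have no random
    initialization, and codeword-loss ties decode to the lowest class
    index.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self.classes_ = np.array(PHANTOM_CLASSES)
        self._scaler: StandardScaler | None = None
        self._learners: list[SVC] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EcocLinearSvm":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        absent = [c for c, n in counts.items() if n < 2]
        if absent:
            raise ValueError(
                f"each class needs >= 2 training rows, got {counts}"
            )
        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)
        self._learners = []
        for k, cls in enumerate(self.classes_):
            target = np.where(y == cls, CODING_MATRIX[k, k], -CODING_MATRIX[k, k])
            learner = SVC(kernel="linear", C=self.C)
            learner.fit(Xs, target)
            self._learners.append(learner)
        return self

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xs = self._scaler.transform(np.asarray(X, dtype=float))
        return np.column_stack([m.decision_function(Xs) for m in self._learners])

    def codeword_losses(self, X: np.ndarray) -> np.ndarray:
        """Aggregate hinge loss of each class codeword for each row."""
        f = self.decision_values(X)  # (n, learners)
        margins = f[:, None, :] * CODING_MATRIX[None, :, :]  # (n, classes, learners)
        return np.maximum(0.0, 1.0 - margins).sum(axis=2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        losses = self.codeword_losses(X)
        return self.classes_[np.argmin(losses, axis=1)]


def train_ecoc_svm(matrix: FeatureMatrix, C: float = 1.0) -> EcocLinearSvm:
    """Fit the ECOC linear SVM on a full feature matrix."""
    return EcocLinearSvm(C=C).fit(matrix.X.to_numpy(), matrix.y)


@dataclass
class ClassifierReport:
    """Holdout confusion matrix, accuracies and per-class metrics.

    ``confusion`` rows are true classes, columns predicted, both in
    (healthy, intermediate, unhealthy) order; accuracies are percentages.
    """

    confusion: np.ndarray
    holdout_accuracy: float
    cv_accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    split_seed: int
    classes: tuple[str, ...] = PHANTOM_CLASSES

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.astype(int).tolist(),
            "holdout_accuracy": self.holdout_accuracy,
            "cv_accuracy": self.cv_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "split_seed": self.split_seed,
        }


def report_from_confusion(confusion: np.ndarray) -> tuple[float, dict, dict, dict]:
    """Accuracy (%) and per-class precision/recall/F1 from a confusion matrix.

    precision_k = C[k,k] / column sum, recall_k = C[k,k] / row sum, F1 the
    harmonic mean (0 when both vanish); empty rows/columns yield 0.
    """
    C = np.asarray(confusion, dtype=float)
    total = C.sum()
    accuracy = 100.0 * np.trace(C) / total if total else 0.0
    precision, recall, f1 = {}, {}, {}
    for k, cls in enumerate(PHANTOM_CLASSES):
        col = C[:, k].sum()
        row = C[k, :].sum()
        p = C[k, k] / col if col else 0.0
        r = C[k, k] / row if row else 0.0
        precision[cls] = float(p)
        recall[cls] = float(r)
        f1[cls] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    return accuracy, precision, recall, f1


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    idx = {c: k for k, c in enumerate(PHANTOM_CLASSES)}
    C = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        C[idx[t], idx[p]] += 1
    return C


def evaluate(
    matrix: FeatureMatrix,
    split_seed: int = 0,
    C: float = 1.0,
    n_folds: int = 5,
    test_size: float = 0.3,
) -> ClassifierReport:
    """Stratified 70/30 holdout plus stratified 5-fold cross-validation.

    The holdout test set provides the confusion matrix and per-class
    metrics; ``cv_accuracy`` is the mean fold accuracy over stratified
    folds, each fold refitting the scaler and learners on its training
    part only.
    """
    X = matrix.X.to_numpy()
    y = matrix.y
    counts = {c: int(np.sum(y == c)) for c in PHANTOM_CLASSES}
    if min(counts.values()) < n_folds:
        raise ValueError(
            f"each class needs >= {n_folds} rows for {n_folds}-fold CV, got {counts}"
        )
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=split_seed
    )
    model = EcocLinearSvm(C=C).fit(X_train, y_train)
    y_pred = model.predict(X_test)
    confusion = _confusion(y_test, y_pred)
    accuracy, precision, recall, f1 = report_from_confusion(confusion)

    folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=split_seed)
    fold_accuracies = []
    for train_idx, test_idx in folds.split(X, y):
        fold_model = EcocLinearSvm(C=C).fit(X[train_idx], y[train_idx])
        fold_pred = fold_model.predict(X[test_idx])
        fold_accuracies.append(float(np.mean(fold_pred == y[test_idx])))
    cv_accuracy = 100.0 * float(np.mean(fold_accuracies))

    return ClassifierReport(
        confusion=confusion,
        holdout_accuracy=accuracy,
        cv_accuracy=cv_accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        split_seed=split_seed,
    )
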