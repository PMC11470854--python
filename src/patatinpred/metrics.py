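"""SVM training, stratified splitting, and confusion-matrix metrics.

The classifier is a support vector machine with one of four kernels
(RBF, linear, sigmoid, polynomial). Default hyper-parameters follow the
classic library convention: C = 1, gamma = 1 / (n_features * Var(X))
("scale"), polynomial degree 3, coef0 = 0. Descriptors are already in
[0, 1], so no feature standardisation is applied by default.

Evaluation metrics are computed directly from the 2x2 confusion matrix:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A zero denominator yields 0 with a warning flag (degenerate folds).
AUC is the trapezoidal area under the ROC curve from continuous
decision scores; an AUC from hard labels is also reported, since the
two differ whenever the score ranking is imperfect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

KERNELS = ("rbf", "linear", "sigmoid", "polynomial")
_SKLEARN_KERNEL = {"polynomial": "poly", "rbf": "rbf", "linear": "linear", "sigmoid": "sigmoid"}


@dataclass(frozen=True)
class SVMConfig:
    """Support vector machine hyper-parameters."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    degree: int = 3
    coef0: float = 0.0
    scale_features: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("numeric gamma must be positive")


@dataclass(frozen=True)
class SplitConfig:
    """Hold-out split: stratified 80/20 by default."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricReport:
    """Scores derived from a confusion matrix (positive class = patatin-like).

    ``macro_*`` fields average the per-class scores of both classes;
    ``auc`` comes from continuous decision scores (None when no scores
    were supplied), ``auc_from_labels`` from the hard predictions.
    """

    precision: float
    recall: float
    f1: float
    accuracy: float
    mcc: float
    auc: float | None = None
    auc_from_labels: float | None = None
    macro_precision: float | None = None
    macro_recall: float | None = None
    macro_f1: float | None = None
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


@dataclass
class TrainedModel:
    """A fitted SVM plus the metadata needed to apply it safely."""

    config: SVMConfig
    estimator: SVC
    feature_names: list[str]
    scaler: StandardScaler | None = None

    def _features(self, matrix: pd.DataFrame) -> np.ndarray:
        cols = [c for c in matrix.columns if c != "label"]
        if cols != self.feature_names:
            raise ValueError("feature columns do not match the training matrix")
        X = matrix[cols].to_numpy()
        return self.scaler.transform(X) if self.scaler is not None else X

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        """Hard labels, as 'positive'/'negative' strings."""
        pred = self.estimator.predict(self._features(matrix))
        return np.where(pred == 1, "positive", "negative")

    def decision_scores(self, matrix: pd.DataFrame) -> np.ndarray:
        """Continuous decision-function values (higher = more positive)."""
        return self.estimator.decision_function(self._features(matrix))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        return joblib.load(path)


def split_dataset(
    matrix: pd.DataFrame, cfg: SplitConfig = SplitConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test partition of an encoded feature matrix.

    A balanced 1170-row matrix at the default 0.8 fraction yields
    exactly 936 training and 234 test rows.
    """
    labels = matrix["label"]
    if labels.value_counts().min() < 2:
        raise ValueError("each class needs at least 2 members to split")
    train, test = train_test_split(
        matrix,
        train_size=cfg.train_fraction,
        stratify=labels if cfg.stratified else None,
        random_state=cfg.seed,
        shuffle=True,
    )
    return train, test


def train_svm(train: pd.DataFrame, cfg: SVMConfig = SVMConfig()) -> TrainedModel:
    """Fit the SVM on an encoded feature matrix with a `label` column."""
    from .encoders import matrix_xy

    X, y = matrix_xy(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    scaler = None
    if cfg.scale_features:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    est = make_svc(cfg).fit(X, y)
    return TrainedModel(
        config=cfg,
        estimator=est,
        feature_names=[c for c in train.columns if c != "label"],
        scaler=scaler,
    )


def make_svc(cfg: SVMConfig) -> SVC:
    return SVC(
        kernel=_SKLEARN_KERNEL[cfg.kernel],
        C=cfg.C,
        gamma=cfg.gamma,
        degree=cfg.degree,
        coef0=cfg.coef0,
        random_state=cfg.seed,
    )


def confusion(model: TrainedModel, test: pd.DataFrame) -> ConfusionMatrix:
    """Confusion matrix of the model on a held-out matrix."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test)
    truth = test["label"].to_numpy()
    return confusion_from_labels(truth, pred)


def confusion_from_labels(
    truth: Sequence[str], pred: Sequence[str]
) -> ConfusionMatrix:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    pos_t = truth == "positive"
    pos_p = pred == "positive"
    return ConfusionMatrix(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
    )


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"zero denominator in {name}; reported as 0")
        return 0.0
    return num / den


def trapezoidal_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by threshold sweep + trapezoid rule."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC needs at least one positive and one negative truth")
    fpr, tpr, _ = roc_curve(y_true, np.asarray(scores, dtype=float))
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> MetricReport:
    """Evaluate all confusion-matrix scores, optionally with AUC.

    ``scores``/``y_true`` (aligned continuous decision values and 0/1
    truths) enable the ROC AUC; the label-based AUC is derived from the
    confusion matrix alone.
    """
    flags: list[str] = []
    tp, fp, fn, tn = cm.TP, cm.FP, cm.FN, cm.TN
    precision = _safe_div(tp, tp + fp, "precision", flags)
    recall = _safe_div(tp, tp + fn, "recall", flags)
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1", flags)
    accuracy = _safe_div(tp + tn, cm.total, "accuracy", flags)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc", flags)

    # negative-class ("non-patatin-like") scores for the macro averages
    neg_precision = _safe_div(tn, tn + fn, "neg precision", flags)
    neg_recall = _safe_div(tn, tn + fp, "neg recall", flags)
    neg_f1 = _safe_div(
        2 * neg_precision * neg_recall, neg_precision + neg_recall, "neg f1", flags
    )

    auc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true required alongside scores for AUC")
        auc = trapezoidal_auc(y_true, scores)

    # ROC through a single operating point: mean of TPR and TNR
    auc_labels = None
    if (tp + fn) > 0 and (tn + fp) > 0:
        auc_labels = 0.5 * (tp / (tp + fn) + tn / (tn + fp))

    return MetricReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        mcc=mcc,
        auc=auc,
        auc_from_labels=auc_labels,
        macro_precision=0.5 * (precision + neg_precision),
        macro_recall=0.5 * (recall + neg_recall),
        macro_f1=0.5 * (f1 + neg_f1),
        warnings=tuple(flags),
    )


def evaluate_model(model: TrainedModel, test: pd.DataFrame) -> MetricReport:
    """Confusion + metrics + score-based AUC in one call."""
    cm = confusion(model, test)
    scores = model.decision_scores(test)
    y_true = (test["label"] == "positive").to_numpy().astype(int)
    return compute_metrics(cm, scores=scores, y_true=y_true)
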