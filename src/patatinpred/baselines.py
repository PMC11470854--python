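"""Comparison classifiers: decision tree, random forest, logistic regression.

Each baseline runs through the identical split/metric pipeline as the
SVM, so reports are directly comparable (paired on the same split and
the same encoded matrix). Hyper-parameters are library defaults (100
trees for the random forest); logistic regression gets a raised
iteration cap so the solver converges on 400-dimensional composition
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .encoders import matrix_xy
from .metrics import MetricReport, compute_metrics, confusion_from_labels

BASELINE_MODELS = ("decision_tree", "random_forest", "logistic_regression")

#: fixed metric order used by the tidy comparison table
METRIC_ORDER = ("accuracy", "precision", "recall", "f1", "mcc", "auc")


@dataclass(frozen=True)
class BaselineConfig:
    model_type: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_type not in BASELINE_MODELS:
            raise ValueError(
                f"model_type must be one of {BASELINE_MODELS}, got {self.model_type!r}"
            )


def make_baseline(cfg: BaselineConfig):
    params = dict(cfg.hyperparameters)
    if cfg.model_type == "decision_tree":
        return DecisionTreeClassifier(random_state=cfg.seed, **params)
    if cfg.model_type == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=cfg.seed, **params)
    params.setdefault("max_iter", 1000)
    return LogisticRegression(random_state=cfg.seed, **params)


def train_and_score_baseline(
    train: pd.DataFrame, test: pd.DataFrame, cfg: BaselineConfig
) -> MetricReport:
    """Fit a baseline on the training matrix and score it on the test matrix."""
    X_tr, y_tr = matrix_xy(train)
    X_te, y_te = matrix_xy(test)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training data must contain both classes")
    est = make_baseline(cfg).fit(X_tr, y_tr)
    pred = est.predict(X_te)
    cm = confusion_from_labels(
        np.where(y_te == 1, "positive", "negative"),
        np.where(pred == 1, "positive", "negative"),
    )
    scores = est.predict_proba(X_te)[:, 1]
    return compute_metrics(cm, scores=scores, y_true=y_te)


def comparison_table(reports: dict[str, MetricReport]) -> pd.DataFrame:
    """Tidy long-format (model, metric, value) table, deterministic order."""
    if not isinstance(reports, dict):
        raise TypeError("reports must map model name -> MetricReport")
    rows = []
    for model in reports:  # preserve caller's insertion order
        metrics = reports[model].as_dict()
        for metric in METRIC_ORDER:
            if metric in metrics:
                rows.append({"model": model, "metric": metric, "value": metrics[metric]})
    return pd.DataFrame(rows, columns=["model", "metric", "value"])
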