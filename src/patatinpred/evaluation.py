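"""Cross-validation, learning curves, and exhaustive C x gamma search.

Ten-fold stratified cross-validation is the workhorse: the data are
split into k class-balanced folds, each fold serves once as validation,
and the fold accuracies are summarised as mean +/- sd. Repeated k-fold
reshuffles and repeats the whole procedure, pooling all r x k scores
for a less noisy estimate. The grid search scores every (C, gamma)
pair on powers-of-ten grids and returns the full accuracy surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.model_selection import learning_curve as _sk_learning_curve

from .encoders import matrix_xy
from .metrics import MetricReport, SVMConfig, confusion_from_labels, compute_metrics, make_svc

#: powers-of-ten grids of the exhaustive hyper-parameter search
DEFAULT_C_GRID = tuple(10.0**e for e in range(-3, 8))  # 1e-3 .. 1e7, 11 values
DEFAULT_GAMMA_GRID = tuple(10.0**e for e in range(-5, 4))  # 1e-5 .. 1e3, 9 values


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    repeats: int = 1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class CVResult:
    """Per-fold accuracies with their mean and (population) sd."""

    per_fold_scores: tuple[float, ...]
    reports: tuple[MetricReport, ...] = ()

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold_scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_fold_scores))

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f}"


@dataclass(frozen=True)
class LearningCurvePoint:
    train_size: int
    train_score_mean: float
    train_score_sd: float
    cv_score_mean: float
    cv_score_sd: float


@dataclass(frozen=True)
class GridSearchResult:
    """Full accuracy surface of the C x gamma search plus the argmax."""

    grid: dict[tuple[float, float], float]
    best_params: tuple[float, float]
    best_score: float

    def surface(self) -> pd.DataFrame:
        """Matrix layout (rows = C, columns = gamma), heat-map ready."""
        Cs = sorted({c for c, _ in self.grid})
        gammas = sorted({g for _, g in self.grid})
        data = [[self.grid[(c, g)] for g in gammas] for c in Cs]
        return pd.DataFrame(data, index=pd.Index(Cs, name="C"),
                            columns=pd.Index(gammas, name="gamma"))


def _splitter(cv_cfg: CVConfig, seed: int):
    cls = StratifiedKFold if cv_cfg.stratified else KFold
    return cls(n_splits=cv_cfg.k, shuffle=True, random_state=seed)


def _check_k(y: np.ndarray, cv_cfg: CVConfig) -> None:
    if cv_cfg.k > len(y):
        raise ValueError(f"k={cv_cfg.k} exceeds the number of samples ({len(y)})")
    if cv_cfg.stratified and cv_cfg.k > int(np.bincount(y).min()):
        raise ValueError("k exceeds the smallest class count under stratification")


def kfold_cv(
    matrix: pd.DataFrame,
    model_cfg: SVMConfig = SVMConfig(),
    cv_cfg: CVConfig = CVConfig(),
    full_reports: bool = False,
) -> CVResult:
    """Single-run stratified k-fold cross-validation (fold score = accuracy)."""
    X, y = matrix_xy(matrix)
    _check_k(y, cv_cfg)
    scores: list[float] = []
    reports: list[MetricReport] = []
    for train_idx, val_idx in _splitter(cv_cfg, cv_cfg.seed).split(X, y):
        est = make_svc(model_cfg).fit(X[train_idx], y[train_idx])
        pred = est.predict(X[val_idx])
        truth = y[val_idx]
        scores.append(float(np.mean(pred == truth)))
        if full_reports:
            cm = confusion_from_labels(
                np.where(truth == 1, "positive", "negative"),
                np.where(pred == 1, "positive", "negative"),
            )
            val_scores = est.decision_function(X[val_idx])
            reports.append(compute_metrics(cm, scores=val_scores, y_true=truth))
    return CVResult(tuple(scores), tuple(reports))


def repeated_kfold_cv(
    matrix: pd.DataFrame,
    model_cfg: SVMConfig = SVMConfig(),
    cv_cfg: CVConfig = CVConfig(repeats=10),
) -> CVResult:
    """r independent reshuffled k-fold runs; all r x k fold scores pooled."""
    if cv_cfg.repeats < 2:
        raise ValueError("repeated CV needs repeats >= 2")
    seeds = np.random.SeedSequence(cv_cfg.seed).generate_state(cv_cfg.repeats) % (2**31)
    pooled: list[float] = []
    for s in seeds:
        run = kfold_cv(matrix, model_cfg, replace(cv_cfg, repeats=1, seed=int(s)))
        pooled.extend(run.per_fold_scores)
    return CVResult(tuple(pooled))


def default_train_sizes(n: int, k: int, points: int = 10) -> list[int]:
    """Evenly spaced training sizes up to the fold-train maximum (k-1)/k * n."""
    upper = int(np.floor((k - 1) / k * n))
    return sorted({int(round(s)) for s in np.linspace(max(2, upper // points), upper, points)})


def learning_curve(
    matrix: pd.DataFrame,
    model_cfg: SVMConfig = SVMConfig(),
    cv_cfg: CVConfig = CVConfig(),
    train_sizes: Sequence[int] | None = None,
) -> list[LearningCurvePoint]:
    """Training vs cross-validation accuracy as the training set grows."""
    X, y = matrix_xy(matrix)
    _check_k(y, cv_cfg)
    max_size = int(np.floor((cv_cfg.k - 1) / cv_cfg.k * len(y)))
    if train_sizes is None:
        train_sizes = default_train_sizes(len(y), cv_cfg.k)
    if any(s > max_size for s in train_sizes):
        raise ValueError(f"train sizes exceed the fold-train maximum ({max_size})")
    sizes, train_scores, cv_scores = _sk_learning_curve(
        make_svc(model_cfg),
        X,
        y,
        train_sizes=np.asarray(train_sizes, dtype=int),
        cv=_splitter(cv_cfg, cv_cfg.seed),
        scoring="accuracy",
        shuffle=True,  # subsampled training portions stay class-mixed
        random_state=cv_cfg.seed,
    )
    return [
        LearningCurvePoint(
            train_size=int(s),
            train_score_mean=float(tr.mean()),
            train_score_sd=float(tr.std()),
            cv_score_mean=float(cv.mean()),
            cv_score_sd=float(cv.std()),
        )
        for s, tr, cv in zip(sizes, train_scores, cv_scores)
    ]


def grid_search(
    matrix: pd.DataFrame,
    kernel: str = "rbf",
    cv_cfg: CVConfig = CVConfig(),
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    model_cfg: SVMConfig | None = None,
) -> GridSearchResult:
    """Exhaustive accuracy surface over every (C, gamma) pair.

    Ties at the maximum resolve to the smallest C, then the smallest
    gamma (candidates are enumerated in that order and the first
    maximum wins).
    """
    if kernel == "linear":
        raise ValueError("the linear kernel has no gamma; grid search needs one")
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("empty grid")
    base = model_cfg or SVMConfig(kernel=kernel)
    X, y = matrix_xy(matrix)
    _check_k(y, cv_cfg)
    param_grid = {"C": sorted(C_grid), "gamma": sorted(gamma_grid)}
    search = GridSearchCV(
        make_svc(replace(base, kernel=kernel)),
        param_grid,
        scoring="accuracy",
        cv=_splitter(cv_cfg, cv_cfg.seed),
        n_jobs=1,
    )
    search.fit(X, y)
    grid = {
        (p["C"], p["gamma"]): float(s)
        for p, s in zip(search.cv_results_["params"], search.cv_results_["mean_test_score"])
    }
    best = (search.best_params_["C"], search.best_params_["gamma"])
    return GridSearchResult(grid=grid, best_params=best, best_score=float(search.best_score_))
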