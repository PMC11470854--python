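"""Mutual-information ranking of feature columns against the class label.

I(X;Y) = D_KL( P(X,Y) || P_X P_Y ) is zero iff X and Y are independent
and grows with dependence; scores are in nats. Two estimators are
exposed: a k-nearest-neighbour estimator (the default; handles the
continuous composition features without binning) and an equal-width
histogram plug-in estimator used as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif

from .encoders import matrix_xy


@dataclass(frozen=True)
class MIRanking:
    """Per-feature MI scores (nats), sorted descending, ties lexicographic."""

    scores: dict[str, float]
    estimator_config: dict = field(default_factory=dict)

    @property
    def order(self) -> list[str]:
        return sorted(self.scores, key=lambda name: (-self.scores[name], name))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.order, "mi": [self.scores[f] for f in self.order]}
        )


def _histogram_mi(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Plug-in MI between a binned continuous feature and binary labels."""
    edges = np.histogram_bin_edges(x, bins=bins)
    xb = np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)
    joint = np.zeros((bins, 2))
    for cls in (0, 1):
        joint[:, cls] = np.bincount(xb[y == cls], minlength=bins)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def mi_ranking(
    matrix: pd.DataFrame,
    estimator: str = "knn",
    n_neighbors: int = 3,
    bins: int = 10,
    seed: int = 0,
) -> MIRanking:
    """Score every feature column by mutual information with the label.

    ``knn`` uses the Kraskov-style k-nearest-neighbour estimator;
    ``histogram`` bins each feature into equal-width bins and applies
    the plug-in formula. Both return nats.
    """
    X, y = matrix_xy(matrix)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; mutual information is undefined")
    if np.bincount(y).min() < 2:
        raise ValueError("need at least 2 samples per class")
    names = [c for c in matrix.columns if c != "label"]
    if estimator == "knn":
        values = mutual_info_classif(
            X, y, n_neighbors=n_neighbors, random_state=seed
        )
        cfg = {"estimator": "knn", "n_neighbors": n_neighbors, "seed": seed}
    elif estimator == "histogram":
        values = np.array([_histogram_mi(X[:, j], y, bins) for j in range(X.shape[1])])
        cfg = {"estimator": "histogram", "bins": bins}
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    values = np.maximum(values, 0.0)
    return MIRanking(dict(zip(names, values.tolist())), estimator_config=cfg)


def top_k(ranking: MIRanking, k: int) -> list[tuple[str, float]]:
    """The k highest-scoring features, in descending order."""
    if not 1 <= k <= len(ranking.scores):
        raise ValueError(f"k must be in [1, {len(ranking.scores)}], got {k}")
    return [(name, ranking.scores[name]) for name in ranking.order[:k]]
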