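"""F-score feature ranking and forward subset selection.

Each feature is scored by the F-score — the squared separation of the two
class means around the overall mean, divided by the pooled within-class
variances:

    F(i) = [(m+_i - m_i)^2 + (m-_i - m_i)^2]
           / [ var+_i + var-_i ]

with var±_i the (n± - 1)-denominator sample variances within each class.
Features are then added to an initially empty set in descending score
order; fivefold-CV accuracy is recorded after each addition, and the prefix
achieving the maximum accuracy is the optimal subset (ties go to the
smallest prefix).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import features as feat
from .svm import SVMConfig, cv_accuracy, grid_search


@dataclass
class FeatureRanking:
    """Per-feature F-scores and the descending-score feature order.

    A feature with perfect class separation and zero within-class variance
    gets an infinite score (flagged in ``infinite``) and ranks first. Ties
    break toward the lower feature index, so rankings are deterministic.
    """

    scores: np.ndarray
    order: np.ndarray
    feature_indices: np.ndarray  # global ids of the scored columns

    @property
    def infinite(self) -> np.ndarray:
        return np.isinf(self.scores)


@dataclass
class FeatureSubset:
    """The selected feature subset, with provenance.

    ``indices`` are global feature ids (0..419 in AAC-then-DPC layout),
    in the ranked order they were added. ``accuracy_curve[k-1]`` is the CV
    accuracy of the top-k prefix, so ``achieved_accuracy`` equals
    ``max(accuracy_curve)`` by construction.
    """

    indices: np.ndarray
    achieved_accuracy: float
    block: str
    accuracy_curve: List[float] = field(default_factory=list)
    config: Optional[SVMConfig] = None
    seed: Optional[int] = None

    @property
    def names(self) -> List[str]:
        return [feat.FEATURE_NAMES[i] for i in self.indices]

    def __len__(self) -> int:
        return len(self.indices)

    def to_text(self) -> str:
        """One feature name per line (persistable subset file)."""
        return "\n".join(self.names) + "\n"

    def sidecar_json(self) -> str:
        payload = {
            "achieved_accuracy": self.achieved_accuracy,
            "block": self.block,
            "seed": self.seed,
            "n_features": len(self.indices),
            "accuracy_curve": self.accuracy_curve,
        }
        if self.config is not None:
            payload["svm_config"] = {"c": self.config.c, "g": self.config.g}
        return json.dumps(payload, indent=2)


def fscore(
    X: np.ndarray,
    y: Sequence[int],
    feature_indices: Optional[Sequence[int]] = None,
) -> FeatureRanking:
    """Rank every column of ``X`` by F-score.

    Requires at least two samples per class (within-class variances need
    n-1 denominators). Zero-numerator features score 0; zero-denominator
    features with a nonzero numerator score +inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos = X[y == 1]
    neg = X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("F-score needs at least 2 samples in each class")
    m = X.mean(axis=0)
    mp, mn = pos.mean(axis=0), neg.mean(axis=0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(
            den > 0, num / np.where(den > 0, den, 1.0),
            np.where(num > 0, np.inf, 0.0),
        )
    order = np.array(
        sorted(range(X.shape[1]), key=lambda i: (-scores[i], i)), dtype=int
    )
    if feature_indices is None:
        feature_indices = np.arange(X.shape[1])
    return FeatureRanking(
        scores=scores,
        order=order,
        feature_indices=np.asarray(feature_indices, dtype=int),
    )


def forward_select(
    X: np.ndarray,
    y: Sequence[int],
    ranking: Optional[FeatureRanking] = None,
    block: str = "custom",
    k_folds: int = 5,
    seed: int = 0,
    config: Optional[SVMConfig] = None,
    retune: bool = False,
    c_grid: Optional[Sequence[float]] = None,
    g_grid: Optional[Sequence[float]] = None,
) -> FeatureSubset:
    """Incremental forward selection along the F-score ranking.

    For k = 1..d the top-k ranked features are evaluated by stratified
    fivefold-CV accuracy of the RBF-SVM; the smallest k attaining the
    maximum accuracy wins. Hyperparameters: by default one grid search on
    the full matrix fixes (c, g) for the whole sweep; with ``retune=True``
    the grid search is re-run at every k (much slower, same folds).

    The same fold split (derived from ``seed``) is reused at every k so the
    sweep is deterministic and prefix accuracies are comparable.
    """
    from .evaluation import kfold_split
    from .svm import DEFAULT_C_GRID, DEFAULT_G_GRID

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if ranking is None:
        ranking = fscore(X, y)
    if ranking.order.size != X.shape[1]:
        raise ValueError("ranking does not cover the feature matrix columns")
    c_grid = DEFAULT_C_GRID if c_grid is None else c_grid
    g_grid = DEFAULT_G_GRID if g_grid is None else g_grid
    folds = kfold_split(y, k=k_folds, seed=seed)

    if config is None and not retune:
        config, _ = grid_search(
            X, y, folds=folds, c_grid=c_grid, g_grid=g_grid
        )

    curve: List[float] = []
    per_k_config: List[SVMConfig] = []
    for k in range(1, X.shape[1] + 1):
        cols = ranking.order[:k]
        Xk = X[:, cols]
        if retune:
            cfg_k, acc = grid_search(
                Xk, y, folds=folds, c_grid=c_grid, g_grid=g_grid
            )
        else:
            cfg_k = config
            acc = cv_accuracy(Xk, y, cfg_k, folds)
        per_k_config.append(cfg_k)
        curve.append(acc)

    best_k = int(np.argmax(curve)) + 1  # argmax returns the first maximum
    cols = ranking.order[:best_k]
    return FeatureSubset(
        indices=ranking.feature_indices[cols],
        achieved_accuracy=float(curve[best_k - 1]),
        block=block,
        accuracy_curve=curve,
        config=per_k_config[best_k - 1],
        seed=seed,
    )
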