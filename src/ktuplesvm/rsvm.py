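"""Linear SVM training and recursive weight-based feature selection (R-SVM).

At each level of a descending ladder of feature counts, a linear soft-margin
SVM is trained on the surviving features, each feature j is scored by its
contribution to the class separation,

    s_j = w_j * (m+_j - m-_j),

where w is the SVM weight vector and m+_j, m-_j are the class means of
feature j over the training rows, and the top-scoring features are kept for
the next level.  The linear kernel keeps model complexity minimal for the
typical regime of few samples and thousands of candidate features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_LADDER",
    "LinearSVMModel",
    "RecursiveSelectionResult",
    "train_linear_svm",
    "feature_scores",
    "build_ladder",
    "rank_features",
    "recursive_select",
    "predict",
]

#: Default descending ladder of feature-selection levels (besides "all").
DEFAULT_LADDER = (1000, 500, 200, 100, 50, 30, 20, 10, 5)

_SOLVER_TOL = 1e-6


@dataclass
class LinearSVMModel:
    """A trained two-class linear decision function f(x) = w.x + b.

    ``dual_coefs`` holds alpha_i * y_i for the support vectors, so the primal
    weights satisfy w = sum_i alpha_i y_i x_i over the support set (this
    reconstruction is an exposed invariant, see :meth:`reconstruct_weights`).
    ``feature_subset`` records which columns of the caller's feature space the
    model was trained on.
    """

    weights: np.ndarray
    bias: float
    dual_coefs: np.ndarray  # alpha_i * y_i per support vector
    support: np.ndarray  # training-row indices of the support vectors
    support_vectors: np.ndarray
    labels: np.ndarray  # y_i of the support vectors
    feature_subset: np.ndarray
    C: float

    @property
    def alphas(self) -> np.ndarray:
        """Non-negative dual coefficients alpha_i of the support vectors."""
        return np.abs(self.dual_coefs)

    def reconstruct_weights(self) -> np.ndarray:
        """Recompute w = sum_i alpha_i y_i x_i from the dual solution."""
        return self.dual_coefs @ self.support_vectors

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"dimension mismatch: model has {self.weights.shape[0]} features, "
                f"input has {X.shape[1]}"
            )
        return X @ self.weights + self.bias


@dataclass
class RecursiveSelectionResult:
    """Nested feature subsets and trained models down the ladder.

    ``subsets[i]`` are the (ascending) column indices surviving at
    ``ladder[i]``; subsets are nested: subsets[i+1] is contained in
    subsets[i].  ``models[i]`` was trained on exactly subsets[i] and
    ``scores[i]`` are its per-feature contribution scores (aligned with
    subsets[i]).
    """

    ladder: list[int]
    subsets: list[np.ndarray]
    models: list[LinearSVMModel]
    scores: list[np.ndarray]

    def level_index(self, level: int) -> int:
        try:
            return self.ladder.index(level)
        except ValueError:
            raise KeyError(f"level {level} not in ladder {self.ladder}") from None


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> LinearSVMModel:
    """Train a linear soft-margin SVM; deterministic given (X, y, C)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    if set(classes.tolist()) != {-1, 1}:
        raise ValueError(f"labels must contain both -1 and +1, got {classes}")
    svc = SVC(kernel="linear", C=C, tol=_SOLVER_TOL, shrinking=True)
    svc.fit(X, y)
    return LinearSVMModel(
        weights=svc.coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        dual_coefs=svc.dual_coef_[0].copy(),
        support=svc.support_.copy(),
        support_vectors=svc.support_vectors_.copy(),
        labels=y[svc.support_].astype(int),
        feature_subset=np.arange(X.shape[1]),
        C=C,
    )


def feature_scores(
    model: LinearSVMModel, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Score each feature as s_j = w_j * (m+_j - m-_j).

    The class means are taken over all training rows of X (which must be the
    matrix the model was trained on, restricted to its feature subset).
    Higher scores mark features whose weighted class-mean separation
    contributes more to the decision function.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y == -1]
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("both classes must be present to compute class means")
    return model.weights * (pos.mean(axis=0) - neg.mean(axis=0))


def build_ladder(
    n_features: int, base: Sequence[int] = DEFAULT_LADDER
) -> list[int]:
    """Descending ladder: all features, then base levels strictly below it."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    levels = sorted({int(b) for b in base if 0 < b < n_features}, reverse=True)
    return [int(n_features)] + levels


def rank_features(
    scores: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Order features by descending score; ties by descending ``|w|`` then
    ascending column position.  Fully deterministic."""
    cols = np.arange(scores.shape[0])
    # np.lexsort: last key is primary.
    return np.lexsort((cols, -np.abs(weights), -scores))


def recursive_select(
    X: np.ndarray,
    y: np.ndarray,
    ladder: Sequence[int],
    C: float = 1.0,
) -> RecursiveSelectionResult:
    """Run recursive feature selection down the ladder.

    The first ladder level must equal the number of columns of X.  At each
    level a fresh SVM is trained on the surviving features and used both for
    scoring (to choose the next subset) and for prediction at that level.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ladder = [int(l) for l in ladder]
    if ladder != sorted(set(ladder), reverse=True):
        raise ValueError(f"ladder must be strictly decreasing: {ladder}")
    if ladder[0] != X.shape[1]:
        raise ValueError(
            f"first ladder level ({ladder[0]}) must equal number of features "
            f"({X.shape[1]})"
        )
    if ladder[-1] < 1:
        raise ValueError("last ladder level must be >= 1")

    current = np.arange(X.shape[1])
    subsets: list[np.ndarray] = []
    models: list[LinearSVMModel] = []
    scores_per_level: list[np.ndarray] = []
    for i, level in enumerate(ladder):
        model = train_linear_svm(X[:, current], y, C=C)
        model.feature_subset = current
        scores = feature_scores(model, X[:, current], y)
        subsets.append(current)
        models.append(model)
        scores_per_level.append(scores)
        if i + 1 < len(ladder):
            order = rank_features(scores, model.weights)
            keep = order[: ladder[i + 1]]
            current = np.sort(current[keep])
    return RecursiveSelectionResult(
        ladder=ladder, subsets=subsets, models=models, scores=scores_per_level
    )


def predict(model: LinearSVMModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels sign(w.x + b) in {-1, +1}; exactly 0 maps to +1."""
    f = model.decision_function(X)
    return np.where(f >= 0, 1, -1)
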