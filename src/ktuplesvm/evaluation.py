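"""Feature-selection-inside leave-one-out cross-validation and final refit.

The LOOCV protocol here is the stringent one ("CV2"): the held-out sample is
removed *before* depth normalization is standardized, before z-scoring is
fitted and before any feature selection, so no information about the test
sample leaks into the selection.  Selecting features on all samples first and
cross-validating afterwards gives optimistic estimates; that biased variant
is deliberately not offered.

After cross-validation, which produces one feature subset per fold, the
recursive selection is re-run once on all samples to obtain the single
feature set and classifier used for predicting new samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import rsvm
from .features import (
    KTupleIndex,
    KTupleMatrix,
    Standardization,
    apply_standardizer,
    build_count_matrix,
    fit_standardizer,
    to_frequencies,
)
from .rsvm import DEFAULT_LADDER, LinearSVMModel, build_ladder, recursive_select
from .simulate import ReadSet

__all__ = [
    "CV2Result",
    "BestResult",
    "FinalModel",
    "loocv_cv2",
    "loocv_cv2_from_frequencies",
    "best_result",
    "final_model",
    "predict_samples",
]


@dataclass
class CV2Result:
    """Per-level LOOCV performance for one tuple length k.

    ``levels`` is the descending ladder (the top entry is the "all features"
    level).  ``predictions[level]`` holds the held-out prediction for each
    sample; a 0 marks a fold whose ladder did not contain that level (this
    can only happen when folds disagree on the number of non-constant
    features).  Error rates are computed over the folds that have the level.
    """

    k: int
    n_samples: int
    levels: list[int]
    y_true: np.ndarray
    predictions: dict[int, np.ndarray]
    fold_subsets: list[dict[int, np.ndarray]]
    error_rates: dict[int, float] = field(default_factory=dict)
    accuracies: dict[int, float] = field(default_factory=dict)
    sensitivities: dict[int, float] = field(default_factory=dict)
    specificities: dict[int, float] = field(default_factory=dict)

    def finalize(self) -> "CV2Result":
        for level in self.levels:
            pred = self.predictions[level]
            have = pred != 0
            y = self.y_true[have]
            p = pred[have]
            correct = p == y
            self.accuracies[level] = float(correct.mean())
            self.error_rates[level] = 1.0 - self.accuracies[level]
            pos, neg = y == 1, y == -1
            self.sensitivities[level] = (
                float(correct[pos].mean()) if pos.any() else float("nan")
            )
            self.specificities[level] = (
                float(correct[neg].mean()) if neg.any() else float("nan")
            )
        return self

    def best_accuracy(self, max_level: int = 200) -> float:
        eligible = [l for l in self.levels if l <= max_level]
        if not eligible:
            raise ValueError(f"no ladder level at or below {max_level}")
        return max(self.accuracies[l] for l in eligible)


@dataclass
class BestResult:
    """The (k, level) pair picked by the best-result priority rule."""

    k: int
    level: int
    accuracy: float
    considered: list[tuple[int, int, float]]  # (k, level, accuracy) candidates


def _fold_result(
    freq: KTupleMatrix,
    y: np.ndarray,
    test_row: int,
    ladder_base: Sequence[int],
    C: float,
    global_params: Optional[Standardization],
) -> tuple[dict[int, int], dict[int, np.ndarray]]:
    """One LOOCV fold: select on the training rows, predict the held-out row."""
    train_rows = np.array([i for i in range(freq.n_samples) if i != test_row])
    params = (
        global_params
        if global_params is not None
        else fit_standardizer(freq, train_rows)
    )
    Z = apply_standardizer(freq, params)
    Xtr = Z.values[train_rows]
    xte = Z.values[test_row]
    ladder = build_ladder(Xtr.shape[1], ladder_base)
    selection = recursive_select(Xtr, y[train_rows], ladder, C=C)
    predictions: dict[int, int] = {}
    subsets: dict[int, np.ndarray] = {}
    for level, subset, model in zip(
        selection.ladder, selection.subsets, selection.models
    ):
        predictions[level] = int(rsvm.predict(model, xte[subset][None, :])[0])
        subsets[level] = Z.columns[subset]
    return predictions, subsets


def loocv_cv2_from_frequencies(
    freq: KTupleMatrix,
    y: np.ndarray,
    ladder_base: Sequence[int] = DEFAULT_LADDER,
    C: float = 1.0,
    standardize_scope: str = "train_only",
) -> CV2Result:
    """CV2 LOOCV on a precomputed per-sample frequency matrix.

    ``standardize_scope`` controls where the z-scoring is fitted:
    ``train_only`` (default) refits it inside every fold on the training rows
    only, keeping the protocol fully leakage-free; ``global`` fits it once on
    all samples, the literal all-samples standardization.
    """
    y = np.asarray(y)
    if freq.n_samples != y.shape[0]:
        raise ValueError("label vector length does not match number of samples")
    for cls in (-1, 1):
        if (y == cls).sum() < 2:
            raise ValueError(f"need at least 2 samples of class {cls:+d} for LOOCV")
    if standardize_scope not in ("train_only", "global"):
        raise ValueError(f"unknown standardize_scope {standardize_scope!r}")
    global_params = (
        fit_standardizer(freq) if standardize_scope == "global" else None
    )

    n = freq.n_samples
    per_fold_preds: list[dict[int, int]] = []
    fold_subsets: list[dict[int, np.ndarray]] = []
    for test_row in range(n):
        predictions, subsets = _fold_result(
            freq, y, test_row, ladder_base, C, global_params
        )
        per_fold_preds.append(predictions)
        fold_subsets.append(subsets)

    # The "all" level can differ between folds when the non-constant feature
    # count does; aggregate every fold's top level under the full-data count.
    full_kept = (
        global_params.kept.size
        if global_params is not None
        else fit_standardizer(freq).kept.size
    )
    all_key = build_ladder(full_kept, ladder_base)[0]
    levels: set[int] = set()
    for preds in per_fold_preds:
        fold_all = max(preds)
        levels.update(l for l in preds if l != fold_all)
        levels.add(all_key)
    ordered = sorted(levels, reverse=True)
    predictions = {l: np.zeros(n, dtype=int) for l in ordered}
    for i, preds in enumerate(per_fold_preds):
        fold_all = max(preds)
        for level, label in preds.items():
            key = all_key if level == fold_all else level
            predictions[key][i] = label
    return CV2Result(
        k=freq.k,
        n_samples=n,
        levels=ordered,
        y_true=y.astype(int),
        predictions=predictions,
        fold_subsets=fold_subsets,
    ).finalize()


def loocv_cv2(
    samples: Sequence[ReadSet],
    k: int,
    ladder_base: Sequence[int] = DEFAULT_LADDER,
    C: float = 1.0,
    standardize_scope: str = "train_only",
) -> CV2Result:
    """CV2 LOOCV straight from labelled read sets (counts k-tuples first)."""
    y = _labels(samples)
    freq = to_frequencies(build_count_matrix(samples, k))
    return loocv_cv2_from_frequencies(
        freq, y, ladder_base=ladder_base, C=C, standardize_scope=standardize_scope
    )


def _labels(samples: Sequence[ReadSet]) -> np.ndarray:
    labels = []
    for s in samples:
        if s.label is None:
            raise ValueError(f"sample {s.sample_id!r} has no class label")
        labels.append(s.label)
    return np.asarray(labels, dtype=int)


def best_result(
    results: Sequence[CV2Result], max_level: int = 200
) -> BestResult:
    """Pick the best (k, level) across tuple lengths.

    Priority: only levels at or below ``max_level`` are considered; among
    those, highest accuracy wins, ties broken by fewer features, then by
    shorter tuple length.
    """
    if not results:
        raise ValueError("no CV2 results given")
    candidates: list[tuple[int, int, float]] = []
    for res in results:
        for level in res.levels:
            if level <= max_level:
                candidates.append((res.k, level, res.accuracies[level]))
    if not candidates:
        raise ValueError(f"no ladder level at or below {max_level} in any result")
    best = max(candidates, key=lambda c: (c[2], -c[1], -c[0]))
    return BestResult(k=best[0], level=best[1], accuracy=best[2], considered=candidates)


@dataclass
class FinalModel:
    """All-samples refit at one ladder level, serializable for later use.

    Carries everything needed to classify a new sample from raw reads: the
    tuple length, the selected words, their depth-normalization-free
    standardization parameters and the linear decision function.
    """

    k: int
    level: int
    C: float
    words: list[str]
    weights: np.ndarray
    bias: float
    feature_means: np.ndarray  # per selected word, on the frequency scale
    feature_stds: np.ndarray
    svm: Optional[LinearSVMModel] = None
    selection: Optional[rsvm.RecursiveSelectionResult] = None

    def predict_frequency_rows(self, freq_rows: np.ndarray) -> np.ndarray:
        z = (freq_rows - self.feature_means) / self.feature_stds
        return np.where(z @ self.weights + self.bias >= 0, 1, -1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "level": self.level,
                "C": self.C,
                "words": self.words,
                "weights": self.weights.tolist(),
                "bias": self.bias,
                "feature_means": self.feature_means.tolist(),
                "feature_stds": self.feature_stds.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FinalModel":
        d = json.loads(text)
        return cls(
            k=d["k"],
            level=d["level"],
            C=d["C"],
            words=list(d["words"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_stds=np.asarray(d["feature_stds"], dtype=float),
        )


def final_model(
    samples: Sequence[ReadSet],
    k: int,
    level: int,
    ladder_base: Sequence[int] = DEFAULT_LADDER,
    C: float = 1.0,
) -> FinalModel:
    """Re-run recursive selection on all samples; return the model at ``level``.

    The standardizer is fitted on all samples, recursive selection runs down
    the full ladder, and the classifier trained at the requested level is
    packaged with its selected words for predicting new samples.
    """
    y = _labels(samples)
    freq = to_frequencies(build_count_matrix(samples, k))
    params = fit_standardizer(freq)
    Z = apply_standardizer(freq, params)
    ladder = build_ladder(Z.values.shape[1], ladder_base)
    if level not in ladder:
        raise ValueError(f"level {level} not in ladder {ladder}")
    selection = recursive_select(Z.values, y, ladder, C=C)
    i = selection.level_index(level)
    subset = selection.subsets[i]
    model = selection.models[i]
    original_cols = Z.columns[subset]
    index = KTupleIndex(k)
    return FinalModel(
        k=k,
        level=level,
        C=C,
        words=[index.word(int(c)) for c in original_cols],
        weights=model.weights.copy(),
        bias=model.bias,
        feature_means=params.mean[original_cols].copy(),
        feature_stds=params.std[original_cols].copy(),
        svm=model,
        selection=selection,
    )


def predict_samples(
    model: FinalModel, samples: Sequence[ReadSet]
) -> tuple[np.ndarray, Optional[dict[str, float]]]:
    """Classify read sets with a final model; metrics if labels are present.

    Returns (predicted labels, metrics) where metrics holds accuracy,
    sensitivity and specificity (class +1 positive) when every sample is
    labelled, else None.
    """
    if not samples:
        return np.zeros(0, dtype=int), None
    index = KTupleIndex(model.k)
    cols = np.array([index.index(w) for w in model.words])
    freq = to_frequencies(build_count_matrix(samples, model.k))
    pred = model.predict_frequency_rows(freq.values[:, cols])
    if any(s.label is None for s in samples):
        return pred, None
    y = _labels(samples)
    correct = pred == y
    pos, neg = y == 1, y == -1
    metrics = {
        "accuracy": float(correct.mean()),
        "sensitivity": float(correct[pos].mean()) if pos.any() else float("nan"),
        "specificity": float(correct[neg].mean()) if neg.any() else float("nan"),
    }
    return pred, metrics
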