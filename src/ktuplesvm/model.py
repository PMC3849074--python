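"""Model/Results facade over the functional pipeline.

:class:`RSVM` is built from labelled read sets (or a sample sheet) for one
tuple length; ``fit()`` runs the recursive feature selection on all samples
and returns an :class:`RSVMResults` holding the per-level models and
selected words; ``loocv()`` returns a :class:`LOOCVResults` with the
cross-validated per-level error rates.  Both results objects render a
``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluation, permutation
from .evaluation import CV2Result, FinalModel
from .features import (
    KTupleIndex,
    apply_standardizer,
    build_count_matrix,
    fit_standardizer,
    to_frequencies,
)
from .io import load_samples, read_sample_sheet
from .rsvm import DEFAULT_LADDER, build_ladder, recursive_select
from .simulate import ReadSet

__all__ = ["RSVM", "RSVMResults", "LOOCVResults"]


class RSVM:
    """Recursive-SVM classifier on k-tuple signatures of one tuple length.

    Parameters
    ----------
    samples:
        Labelled read sets (labels +1 / -1).
    k:
        Tuple length; features are the 4^k words.
    ladder_base:
        Descending feature-count levels tried below "all features".
    C:
        Soft-margin penalty of the linear SVM.
    standardize_scope:
        Where the per-feature z-scoring is fitted during LOOCV:
        ``train_only`` (leakage-free, default) or ``global``.
    """

    def __init__(
        self,
        samples: Sequence[ReadSet],
        k: int,
        ladder_base: Sequence[int] = DEFAULT_LADDER,
        C: float = 1.0,
        standardize_scope: str = "train_only",
    ):
        if not samples:
            raise ValueError("no samples given")
        self.samples = list(samples)
        self.k = k
        self.ladder_base = tuple(ladder_base)
        self.C = C
        self.standardize_scope = standardize_scope
        self.y = np.asarray([s.label for s in samples], dtype=int)
        self._freq = None

    @classmethod
    def from_sample_sheet(cls, path, k: int, **kwargs) -> "RSVM":
        sheet = read_sample_sheet(path)
        return cls(load_samples(sheet), k=k, **kwargs)

    @property
    def frequencies(self):
        """Per-sample k-tuple frequency matrix (computed once, cached)."""
        if self._freq is None:
            self._freq = to_frequencies(build_count_matrix(self.samples, self.k))
        return self._freq

    def fit(self, level: Optional[int] = None) -> "RSVMResults":
        """Run recursive selection on all samples.

        ``level`` picks which ladder level the packaged final classifier uses
        (default: the smallest level, i.e. the fewest features).
        """
        freq = self.frequencies
        params = fit_standardizer(freq)
        Z = apply_standardizer(freq, params)
        ladder = build_ladder(Z.values.shape[1], self.ladder_base)
        if level is None:
            level = ladder[-1]
        selection = recursive_select(Z.values, self.y, ladder, C=self.C)
        i = selection.level_index(level)
        index = KTupleIndex(self.k)
        cols = Z.columns[selection.subsets[i]]
        final = FinalModel(
            k=self.k,
            level=level,
            C=self.C,
            words=[index.word(int(c)) for c in cols],
            weights=selection.models[i].weights.copy(),
            bias=selection.models[i].bias,
            feature_means=params.mean[cols].copy(),
            feature_stds=params.std[cols].copy(),
            svm=selection.models[i],
            selection=selection,
        )
        return RSVMResults(self, selection, Z, final)

    def loocv(self) -> "LOOCVResults":
        """Feature-selection-inside LOOCV (CV2) at this tuple length."""
        res = evaluation.loocv_cv2_from_frequencies(
            self.frequencies,
            self.y,
            ladder_base=self.ladder_base,
            C=self.C,
            standardize_scope=self.standardize_scope,
        )
        return LOOCVResults(self, res)

    def permutation_test(
        self,
        n_perm: int = 1000,
        rng: Optional[np.random.Generator] = None,
        max_level: int = 200,
    ):
        """Label-permutation null of the best LOOCV accuracy (this k only)."""
        return permutation.permutation_test(
            self.samples,
            k_grid=[self.k],
            n_perm=n_perm,
            rng=rng,
            ladder_base=self.ladder_base,
            C=self.C,
            standardize_scope=self.standardize_scope,
            max_level=max_level,
        )


class RSVMResults:
    """All-samples recursive-selection results for one tuple length."""

    def __init__(self, model: RSVM, selection, Z, final: FinalModel):
        self.model = model
        self.selection = selection
        self._Z = Z
        self.final = final
        self.k = model.k
        self.ladder = selection.ladder

    def words_at(self, level: int) -> list[str]:
        """The k-tuple words selected at a ladder level (ascending index order)."""
        i = self.selection.level_index(level)
        index = KTupleIndex(self.k)
        cols = self._Z.columns[self.selection.subsets[i]]
        return [index.word(int(c)) for c in cols]

    def predict(self, samples: Sequence[ReadSet]):
        """Classify new read sets with the packaged final classifier."""
        return evaluation.predict_samples(self.final, samples)

    def summary(self) -> pd.DataFrame:
        """One row per ladder level: training accuracy and margin-norm."""
        rows = []
        for level, subset, m in zip(
            self.selection.ladder, self.selection.subsets, self.selection.models
        ):
            Xsub = self._Z.values[:, subset]
            pred = np.where(Xsub @ m.weights + m.bias >= 0, 1, -1)
            rows.append(
                {
                    "level": level,
                    "train_accuracy": float((pred == self.model.y).mean()),
                    "n_support_vectors": int(m.support.size),
                    "weight_norm": float(np.linalg.norm(m.weights)),
                }
            )
        return pd.DataFrame(rows)


class LOOCVResults:
    """Cross-validated per-level performance for one tuple length."""

    def __init__(self, model: RSVM, result: CV2Result):
        self.model = model
        self.result = result
        self.k = result.k

    @property
    def error_rates(self) -> dict[int, float]:
        return self.result.error_rates

    @property
    def accuracies(self) -> dict[int, float]:
        return self.result.accuracies

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "level": level,
                "error_rate": self.result.error_rates[level],
                "accuracy": self.result.accuracies[level],
                "sensitivity": self.result.sensitivities[level],
                "specificity": self.result.specificities[level],
            }
            for level in self.result.levels
        ]
        return pd.DataFrame(rows)
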