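"""Label-permutation significance test for the best LOOCV accuracy.

With few samples and a huge candidate feature space, a wrapper method that
selects features while training can reach seemingly good accuracies by
chance.  The null distribution of the "best result" accuracy is estimated by
permuting the class labels (keeping class sizes fixed), rerunning the full
feature-selection-inside LOOCV over the whole tuple-length grid for each
permutation, and recording the best accuracy each time.

The p-value is the fraction of permutations whose best accuracy is at least
the observed one; with zero exceedances it is reported as the bound
``< 1/n_perm``, the smallest value the experiment can resolve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .evaluation import (
    CV2Result,
    best_result,
    loocv_cv2_from_frequencies,
)
from .features import KTupleMatrix, build_count_matrix, to_frequencies
from .rsvm import DEFAULT_LADDER
from .simulate import ReadSet

__all__ = ["PermutationResult", "permute_labels", "permutation_test"]


@dataclass
class PermutationResult:
    n_perm: int
    null_accuracies: np.ndarray
    observed: float
    p_value: float  # exceedance fraction; 0.0 means "below resolution"
    p_value_str: str  # the reported value, a bound when the count is zero
    observed_best: Optional[object] = None  # BestResult on the true labels


def permute_labels(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A uniform random permutation of the labels (multiset preserved)."""
    y = np.asarray(y)
    return y[rng.permutation(y.shape[0])]


def _best_accuracy_over_grid(
    freqs: Sequence[KTupleMatrix],
    y: np.ndarray,
    ladder_base: Sequence[int],
    C: float,
    standardize_scope: str,
    max_level: int,
) -> tuple[float, list[CV2Result]]:
    results = [
        loocv_cv2_from_frequencies(
            f, y, ladder_base=ladder_base, C=C, standardize_scope=standardize_scope
        )
        for f in freqs
    ]
    return best_result(results, max_level=max_level).accuracy, results


def permutation_test(
    samples: Sequence[ReadSet],
    k_grid: Sequence[int],
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    ladder_base: Sequence[int] = DEFAULT_LADDER,
    C: float = 1.0,
    standardize_scope: str = "train_only",
    max_level: int = 200,
) -> PermutationResult:
    """Estimate the null distribution of the best LOOCV accuracy.

    The k-tuple count and frequency matrices depend only on the reads, never
    on the labels, so they are computed once and reused across permutations;
    everything downstream (per-fold standardization included) is recomputed
    for every permuted label vector.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray([s.label for s in samples], dtype=int)
    freqs = [to_frequencies(build_count_matrix(samples, k)) for k in k_grid]
    observed, observed_results = _best_accuracy_over_grid(
        freqs, y, ladder_base, C, standardize_scope, max_level
    )
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = permute_labels(y, rng)
        null[i], _ = _best_accuracy_over_grid(
            freqs, yp, ladder_base, C, standardize_scope, max_level
        )
    exceed = int((null >= observed).sum())
    p = exceed / n_perm
    p_str = f"< {1 / n_perm:g}" if exceed == 0 else f"{p:g}"
    return PermutationResult(
        n_perm=n_perm,
        null_accuracies=null,
        observed=observed,
        p_value=p,
        p_value_str=p_str,
        observed_best=best_result(observed_results, max_level=max_level),
    )
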