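"""k-tuple counting and the two-step feature standardization.

Features are the 4^k DNA words of length k, indexed lexicographically with
A<C<G<T.  Words are counted literally in every read with overlapping windows
and no reverse-complement collapsing: strand information enters through the
data itself, because reads are sequenced from both strands.  Counts are then
(1) normalized per sample by the total window count, removing sequencing-depth
differences, and (2) z-scored per feature across the samples used for fitting
(population variance, so fitted columns have variance exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dna import decode, encode
from .simulate import ReadSet

__all__ = [
    "KTupleIndex",
    "KTupleMatrix",
    "Standardization",
    "MAX_K",
    "filter_reads",
    "count_ktuples",
    "build_count_matrix",
    "to_frequencies",
    "fit_standardizer",
    "apply_standardizer",
]

#: Largest supported tuple length (dense 4^k columns).
MAX_K = 10

#: Columns whose per-feature standard deviation falls at or below this value
#: are flagged constant and dropped (their z-score is undefined).
_CONSTANT_STD_TOL = 0.0


class KTupleIndex:
    """Bijection between DNA words of length k and columns 0..4^k-1.

    The ordering is lexicographic with A<C<G<T, i.e. a word's index is its
    base-4 value under A=0, C=1, G=2, T=3.
    """

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > MAX_K:
            raise ValueError(f"k={k} not supported (dense matrices only up to k={MAX_K})")
        self.k = k
        self.n_words = 4**k

    def index(self, word: str) -> int:
        if len(word) != self.k:
            raise ValueError(f"word {word!r} does not have length {self.k}")
        codes = encode(word)
        if (codes == 255).any():
            raise ValueError(f"word {word!r} contains non-ACGT characters")
        return int(codes.astype(np.int64) @ (4 ** np.arange(self.k - 1, -1, -1)))

    def word(self, index: int) -> str:
        if not 0 <= index < self.n_words:
            raise IndexError(f"index {index} out of range for k={self.k}")
        codes = (index // 4 ** np.arange(self.k - 1, -1, -1)) % 4
        return decode(codes)

    def words(self) -> list[str]:
        return [self.word(i) for i in range(self.n_words)]


@dataclass
class Standardization:
    """Per-feature mean/std fitted on a set of rows, with constant columns flagged."""

    mean: np.ndarray
    std: np.ndarray
    kept: np.ndarray  # column positions with non-zero std, in ascending order
    n_fit_rows: int


@dataclass
class KTupleMatrix:
    """samples x features matrix in one of three states.

    ``counts``: non-negative integer window counts; ``frequencies``: rows sum
    to 1; ``standardized``: z-scored per feature over the fitting rows, with
    constant features dropped.  ``columns`` maps matrix columns back to the
    original k-tuple indices (identity until constants are dropped).
    """

    sample_ids: list[str]
    k: int
    values: np.ndarray
    state: str  # counts | frequencies | standardized
    columns: np.ndarray = field(default=None)  # type: ignore[assignment]
    standardization: Optional[Standardization] = None

    def __post_init__(self) -> None:
        if self.columns is None:
            self.columns = np.arange(self.values.shape[1])

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def words(self) -> list[str]:
        idx = KTupleIndex(self.k)
        return [idx.word(int(c)) for c in self.columns]


def filter_reads(reads: Sequence[str]) -> list[str]:
    """Drop reads with any non-ACGT character; uppercase the rest.

    Ambiguity codes (N and the other IUPAC letters) mean the read's k-tuple
    content is not fully determined, so the whole read is discarded.  Order
    is preserved.
    """
    kept = []
    for read in reads:
        codes = encode(read)
        if codes.size and not (codes == 255).any():
            kept.append(read.upper())
    return kept


def count_ktuples(reads: Sequence[str], k: int) -> np.ndarray:
    """Count every k-tuple occurrence across reads (overlaps included).

    Each read of length L contributes max(0, L-k+1) windows; reads are counted
    as-is on their own strand.  Returns a dense int64 vector of length 4^k.
    """
    index = KTupleIndex(k)  # validates k
    counts = np.zeros(index.n_words, dtype=np.int64)
    if not reads:
        return counts
    # Concatenate reads with a sentinel so windows never span two reads.
    joined = "\0".join(reads)
    codes = encode(joined).astype(np.int64)
    if codes.size < k:
        return counts
    m = codes.size - k + 1
    window_codes = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for i in range(k):
        seg = codes[i : i + m]
        seg_valid = seg != 255
        valid &= seg_valid
        window_codes = window_codes * 4 + np.where(seg_valid, seg, 0)
    counts += np.bincount(window_codes[valid], minlength=index.n_words)
    return counts


def build_count_matrix(samples: Sequence[ReadSet], k: int) -> KTupleMatrix:
    """Stack per-sample k-tuple count vectors into a samples x 4^k matrix.

    Reads are N-filtered first.  A sample with no countable window (no reads,
    or all reads shorter than k) is an error naming the sample.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_ids: {dupes}")
    rows = []
    for sample in samples:
        row = count_ktuples(filter_reads(sample.reads), k)
        if row.sum() == 0:
            raise ValueError(
                f"sample {sample.sample_id!r} has no countable {k}-tuple windows"
            )
        rows.append(row)
    return KTupleMatrix(sample_ids=ids, k=k, values=np.vstack(rows), state="counts")


def to_frequencies(matrix: KTupleMatrix) -> KTupleMatrix:
    """Normalize each row by its total window count (depth normalization)."""
    if matrix.state != "counts":
        raise ValueError(f"expected a counts matrix, got state={matrix.state!r}")
    totals = matrix.values.sum(axis=1, keepdims=True).astype(float)
    if (totals == 0).any():
        bad = [matrix.sample_ids[i] for i in np.where(totals[:, 0] == 0)[0]]
        raise ValueError(f"zero-sum rows for samples: {bad}")
    return KTupleMatrix(
        sample_ids=list(matrix.sample_ids),
        k=matrix.k,
        values=matrix.values / totals,
        state="frequencies",
        columns=matrix.columns.copy(),
    )


def fit_standardizer(
    matrix: KTupleMatrix, fit_rows: Optional[Sequence[int]] = None
) -> Standardization:
    """Fit per-feature mean and population std over the given rows.

    Features whose std is zero on the fit rows are flagged constant; they are
    dropped when the standardizer is applied.
    """
    if matrix.state != "frequencies":
        raise ValueError(f"expected a frequencies matrix, got state={matrix.state!r}")
    rows = np.arange(matrix.n_samples) if fit_rows is None else np.asarray(fit_rows)
    if rows.size < 2:
        raise ValueError("need at least 2 fit rows to standardize")
    sub = matrix.values[rows]
    mean = sub.mean(axis=0)
    std = sub.std(axis=0)  # population (divide-by-n) variance
    kept = np.where(std > _CONSTANT_STD_TOL)[0]
    return Standardization(mean=mean, std=std, kept=kept, n_fit_rows=int(rows.size))


def apply_standardizer(
    matrix: KTupleMatrix, params: Standardization
) -> KTupleMatrix:
    """Z-score features using fitted params, dropping constant columns."""
    if matrix.state != "frequencies":
        raise ValueError(f"expected a frequencies matrix, got state={matrix.state!r}")
    if matrix.values.shape[1] != params.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix has {matrix.values.shape[1]} columns, "
            f"standardizer was fitted on {params.mean.shape[0]}"
        )
    kept = params.kept
    values = (matrix.values[:, kept] - params.mean[kept]) / params.std[kept]
    return KTupleMatrix(
        sample_ids=list(matrix.sample_ids),
        k=matrix.k,
        values=values,
        state="standardized",
        columns=matrix.columns[kept],
        standardization=params,
    )
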