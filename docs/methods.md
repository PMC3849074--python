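# Methods

## Model and procedure

The classifier works on k-tuple (k-mer) frequency signatures counted
directly from short reads, with no assembly, mapping or reference
database. For a fixed tuple length k all 4^k words, indexed
lexicographically with A<C<G<T, are candidate features. Counting uses
every overlapping window of every read; a read of length L contributes
L−k+1 windows and reads containing any non-ACGT character are discarded
whole (an ambiguity code leaves the read's word content undetermined; the
rule generalizes the usual N-filter to all IUPAC codes). Words are
counted literally, with no reverse-complement collapsing: because reads
are sequenced from both strands, a motif and its reverse complement both
appear in the data and both can be selected as features — which is itself
informative and is visible in the benchmark results below.

Two normalization steps follow. Per sample, counts are divided by the
sample's total window count, which removes sequencing-depth differences
(the pipeline is exactly invariant to duplicating every read). Per
feature, values are z-scored to mean 0, variance 1 over the samples used
for fitting; the variance is the population (divide-by-n) form so that
fitted columns have variance exactly 1. Features constant on the fitting
rows have no defined z-score and are dropped; the dropped set is recorded
and applied consistently to held-out samples.

Classification and feature selection are wrapped together (recursive SVM).
A linear soft-margin SVM is trained on the surviving features; with the
dual solution αᵢ the primal weights are w = Σᵢ αᵢyᵢxᵢ, and each feature j
is scored by its weighted class-mean separation

    s_j = w_j (m⁺_j − m⁻_j),

the product of the SVM weight and the difference of class means of the
standardized feature. The top-scoring features survive to the next level
of the descending ladder {all, 1000, 500, 200, 100, 50, 30, 20, 10, 5};
when fewer features are available than a ladder entry, the ladder starts
at the available count and keeps only the smaller entries. One SVM is
trained per level and used both for scoring and for prediction at that
level. Ranking ties are broken by larger |w_j|, then lower column index,
making selection fully deterministic; subsets are nested down the ladder
by construction.

Performance is estimated by leave-one-out cross-validation with the
selection *inside* the loop: the held-out sample is removed before the
z-scoring is fitted and before any selection. Selecting features first
and cross-validating afterwards re-uses the test sample's values during
selection and is optimistic on pure-noise data — this contrast is pinned
by a property test. The "best result" across tuple lengths is chosen by
the priority rule: among levels ≤ 200 (inclusive), highest accuracy, then
fewest features, then shortest tuple length. After cross-validation the
recursive selection is re-run once on all samples to produce the single
reportable feature set and classifier; this refit is what `fit`/
`final_model` serialize and what `predict` applies to new samples.

Statistical significance of a best accuracy is assessed by permuting the
class labels (class sizes preserved), re-running the entire
cross-validated pipeline per permutation, and reporting
p = #{null ≥ observed}/n_perm. With zero exceedances the result is
reported as the bound "< 1/n_perm" — the experiment cannot resolve
smaller values. Count and frequency matrices do not depend on labels and
are computed once per permutation study; an equivalence test checks the
cached path against full recomputation.

## Tunable parameters

- **k (tuple length)**, typically scanned over a grid (default 3–8).
  Feature count is 4^k; dense matrices are supported up to k = 10.
  Discrimination is best when k matches the length of the underlying
  discriminative motifs.
- **C (soft-margin penalty)**, default 1.0. The benchmark problems are
  nearly separable at strong signal and results are insensitive to C
  there; it is exposed for harder data.
- **Ladder**, default {all, 1000, 500, 200, 100, 50, 30, 20, 10, 5}.
- **standardize_scope**: `train_only` (default) refits the z-scoring
  inside each cross-validation fold, keeping the estimate strictly
  leakage-free; `global` fits it once on all samples — the literal
  all-samples standardization — at the cost of a small information leak.
- **max_level** for the best-result rule, default 200 (inclusive).
- Simulator: genomes per class (default 25), genome length (10,000),
  base probabilities (uniform), read length (50 bp), coverage (10×),
  seed length/count/density per class.

## The simulator

The generator emulates two groups of similar genomes that differ only in
short characteristic motifs: i.i.d. background bases, seed motifs
overwritten at positions drawn uniformly (later insertions may overwrite
earlier ones; the insertion count is round(density·n/l), half away from
zero, so the realized density matches the target as closely as possible),
and error-free reads with uniform start positions and a fair strand coin,
sampled with replacement. Defaults are the benchmark conditions: 25
genomes per class, n = 10,000, uniform composition, 50 bp reads at 10×
(2,000 reads per sample).

What it deliberately does not emulate: sequencing errors and quality
variation, paired ends, non-uniform fragment models, real taxon abundance
structure, shared homology between classes beyond the i.i.d. background.
Passing the benchmark suite therefore shows the pipeline recovers planted
compositional signal at realistic coverage; it does not by itself
establish performance on real microbiome data, where signals are weaker
and confounded.

Random seed motifs are drawn uniformly over ACGT words with rejection so
that no drawn motif equals, or is the reverse complement of, another
drawn or excluded motif; in the two-class design this keeps the class
signatures genuinely disjoint even though reads come from both strands.

## Numerical choices

- SVM solver: libsvm's SMO (scikit-learn `SVC`, linear kernel),
  tolerance 1e-6, no stochastic subsampling — training is deterministic
  given (X, y, C). The dual coefficients are retained and the
  reconstruction w = Σ αᵢyᵢxᵢ is asserted (rtol 1e-6) in tests.
- Decision values exactly 0 predict class +1 (documented convention).
- Class encoding: class 1 ↦ +1 (positive for sensitivity), class 2 ↦ −1.
- Frequencies must come from rows with at least one countable window;
  zero-window samples are a hard error naming the sample.
- Counting uses a vectorized rolling base-4 code over the concatenated
  reads with a sentinel between reads, verified against a brute-force
  substring-enumeration oracle exhaustively for k ≤ 3.
- Accuracy is stored at full precision; tables render at 2 decimals.

## Design choices where the design was open

- **Score formula.** "Difference between the classes weighted by the
  weight" is implemented as s_j = w_j(m⁺_j − m⁻_j); this is the single
  supported criterion.
- **Per-fold ladders.** The ladder is rebuilt per cross-validation fold
  from that fold's non-constant feature count. Folds can in principle
  disagree on the top ("all") level; all top levels are aggregated under
  the all-samples count. With the benchmark's sample sizes and coverages
  the non-constant count is the full 4^k for every fold at k ≤ 8, so this
  is a corner-case rule, not a practical one.
- **Best-result bound inclusive.** "Below 200" is implemented as ≤ 200 so
  that a 200-feature level is itself eligible.
- **Retraining.** At each ladder level one SVM serves both scoring and
  prediction; no second fit between selection and prediction.
- **Permutations re-fit everything label-dependent.** With `train_only`
  scope the per-fold standardizer depends only on which rows are in the
  training fold, not on labels, but it is recomputed per fold regardless;
  only the label-free count/frequency matrices are cached.
- **Model facade.** The library is also exposed as a model object
  (`RSVM(samples, k)`) whose `fit()` and `loocv()` return results objects
  with `summary()` tables, alongside the functional API and the CLI.

## Problem sizes used in the shipped benchmarks

The test suite and `scripts/acceptance.py` run the simulation study at
its native size (25+25 samples, n = 10,000, 2,000 reads per sample) with
the tuple-length grid 4–7 for the sweep experiments; a full 44-experiment
sweep takes on the order of 10 minutes on one CPU. Property tests use
miniature datasets (hundreds of bases, handfuls of samples) chosen to
exercise the same code paths in milliseconds.

## Known limitations

- Binary classification only; no multiclass, no nonlinear kernels, no
  probability calibration, no voting-based final classifier.
- Dense feature matrices bound practical tuple length at k ≤ 10.
- The count of perfect experiments in a sweep is a sum of Bernoulli
  outcomes over borderline configurations and is therefore stochastic:
  at intermediate seed densities, single realizations under different
  generator seeds can differ from each other by one or two experiments.
  Headline counts from any one seed should be read with that spread in
  mind.
- Selected k-tuple words are statistical discriminators; the package
  offers no biological interpretation of them.
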