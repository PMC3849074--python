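"""CV2 LOOCV, best-result rule, final refit and prediction tests."""

import numpy as np
import pytest

from ktuplesvm.evaluation import (
    CV2Result,
    best_result,
    final_model,
    loocv_cv2,
    loocv_cv2_from_frequencies,
    predict_samples,
)
from ktuplesvm.features import build_count_matrix, to_frequencies
from ktuplesvm.simulate import ReadSet, SeedSpec, SimulationConfig, generate_dataset

from conftest import MASTER_SEED, noise_samples, tiny_dataset


def disjoint_content_samples():
    """2+2 samples whose k-mer content is disjoint between classes."""
    return [
        ReadSet("a1", ["AAAAACAAAAAC"], label=1),
        ReadSet("a2", ["AACAAAAACAAA"], label=1),
        ReadSet("b1", ["GGGGGTGGGGGT"], label=-1),
        ReadSet("b2", ["GGTGGGGGTGGG"], label=-1),
    ]


class TestLoocvCV2:
    def test_trivially_separated_classes_have_zero_error(self):
        res = loocv_cv2(disjoint_content_samples(), k=2)
        assert all(err == 0.0 for err in res.error_rates.values())

    def test_one_heldout_prediction_per_sample_per_level(self):
        samples, _ = tiny_dataset()
        res = loocv_cv2(samples, k=2)
        for level in res.levels:
            assert res.predictions[level].shape == (len(samples),)
            assert set(res.predictions[level]) <= {-1, 1}
            assert 0.0 <= res.error_rates[level] <= 1.0

    def test_no_leakage_from_held_out_sample(self):
        # Replacing the held-out sample's reads must leave the training-fold
        # feature selection untouched.
        samples, _ = tiny_dataset()
        res = loocv_cv2(samples, k=2)
        corrupted = list(samples)
        corrupted[0] = ReadSet(
            samples[0].sample_id, ["ACGT" * 12] * 8, samples[0].label
        )
        res2 = loocv_cv2(corrupted, k=2)
        for level in res.fold_subsets[0]:
            np.testing.assert_array_equal(
                res.fold_subsets[0][level], res2.fold_subsets[0][level]
            )

    def test_reproducible_bit_for_bit(self):
        samples, _ = tiny_dataset()
        a = loocv_cv2(samples, k=3)
        b = loocv_cv2(samples, k=3)
        assert a.error_rates == b.error_rates
        for level in a.levels:
            np.testing.assert_array_equal(a.predictions[level], b.predictions[level])

    def test_randomized_labels_score_near_chance(self):
        # Signal-free data with shuffled labels: mean LOOCV accuracy across
        # repeated draws sits near 0.5 at every level.
        rng = np.random.default_rng(MASTER_SEED)
        samples = noise_samples(n_per_class=5)
        freq = to_frequencies(build_count_matrix(samples, 2))
        per_run_best = []
        for _ in range(60):
            y = rng.permutation(np.repeat([1, -1], 5))
            res = loocv_cv2_from_frequencies(freq, y)
            per_run_best.append(np.mean(list(res.accuracies.values())))
        assert 0.35 < np.mean(per_run_best) < 0.65

    def test_small_class_rejected(self):
        samples = disjoint_content_samples()[:3]
        with pytest.raises(ValueError):
            loocv_cv2(samples, k=2)

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            loocv_cv2(disjoint_content_samples(), k=2, standardize_scope="folds")

    def test_biased_protocol_is_optimistic_on_permuted_labels(self):
        # Selecting features on all samples before cross-validating (the
        # leaky "CV1" protocol) must look at least as good as CV2 on
        # label-permuted data, on average.
        from ktuplesvm.features import apply_standardizer, fit_standardizer
        from ktuplesvm.rsvm import build_ladder, recursive_select, train_linear_svm

        rng = np.random.default_rng(MASTER_SEED)
        samples = noise_samples(n_per_class=5)
        freq = to_frequencies(build_count_matrix(samples, 2))

        def cv1_accuracy(y, level=5):
            params = fit_standardizer(freq)
            Z = apply_standardizer(freq, params)
            ladder = build_ladder(Z.values.shape[1])
            sel = recursive_select(Z.values, y, ladder)
            subset = sel.subsets[sel.level_index(level)]
            correct = 0
            for i in range(len(y)):
                train = np.delete(np.arange(len(y)), i)
                m = train_linear_svm(Z.values[np.ix_(train, subset)], y[train])
                f = Z.values[i, subset] @ m.weights + m.bias
                correct += int((1 if f >= 0 else -1) == y[i])
            return correct / len(y)

        diffs = []
        for _ in range(30):
            y = rng.permutation(np.repeat([1, -1], 5))
            cv2_acc = loocv_cv2_from_frequencies(freq, y).accuracies[5]
            diffs.append(cv1_accuracy(y) - cv2_acc)
        assert np.mean(diffs) >= 0.0


def _fake_result(k, accuracies):
    levels = sorted(accuracies, reverse=True)
    n = 10
    res = CV2Result(
        k=k,
        n_samples=n,
        levels=levels,
        y_true=np.repeat([1, -1], n // 2),
        predictions={l: np.ones(n, dtype=int) for l in levels},
        fold_subsets=[],
    )
    res.accuracies = dict(accuracies)
    res.error_rates = {l: 1 - a for l, a in accuracies.items()}
    return res


class TestBestResult:
    def test_level_cap_filters_large_levels(self):
        res = _fake_result(6, {4096: 1.0, 1000: 1.0, 200: 0.9, 5: 0.8})
        best = best_result([res])
        assert (best.k, best.level, best.accuracy) == (6, 200, 0.9)

    def test_highest_accuracy_then_fewest_features_then_shortest_k(self):
        r5 = _fake_result(5, {100: 0.9, 20: 1.0, 5: 0.9})
        r6 = _fake_result(6, {100: 1.0, 20: 1.0, 5: 1.0})
        best = best_result([r5, r6])
        assert (best.k, best.level) == (6, 5)
        tie5 = _fake_result(5, {20: 1.0})
        tie6 = _fake_result(6, {20: 1.0})
        assert best_result([tie6, tie5]).k == 5

    def test_level_200_is_inclusive(self):
        res = _fake_result(7, {500: 1.0, 200: 0.95, 100: 0.9})
        assert best_result([res]).level == 200

    def test_single_entry(self):
        res = _fake_result(4, {5: 0.7})
        best = best_result([res])
        assert (best.k, best.level, best.accuracy) == (4, 5, 0.7)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            best_result([])


class TestFinalModel:
    def test_refit_is_deterministic(self):
        samples, _ = tiny_dataset()
        a = final_model(samples, k=2, level=5)
        b = final_model(samples, k=2, level=5)
        assert a.words == b.words
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_level_equal_to_total_feature_count(self):
        samples, _ = tiny_dataset()
        freq = to_frequencies(build_count_matrix(samples, 2))
        n_features = freq.values.shape[1]
        model = final_model(samples, k=2, level=n_features)
        assert len(model.words) == n_features

    def test_level_not_in_ladder_rejected(self):
        samples, _ = tiny_dataset()
        with pytest.raises(ValueError):
            final_model(samples, k=2, level=7)

    def test_json_roundtrip_predicts_identically(self):
        from ktuplesvm.evaluation import FinalModel

        samples, _ = tiny_dataset()
        model = final_model(samples, k=2, level=5)
        clone = FinalModel.from_json(model.to_json())
        pred_a, _ = predict_samples(model, samples)
        pred_b, _ = predict_samples(clone, samples)
        np.testing.assert_array_equal(pred_a, pred_b)


class TestPredictSamples:
    def test_training_accuracy_on_separable_fit(self):
        samples = disjoint_content_samples()
        model = final_model(samples, k=2, level=5)
        pred, metrics = predict_samples(model, samples)
        assert metrics["accuracy"] == 1.0
        np.testing.assert_array_equal(pred, [1, 1, -1, -1])

    def test_empty_sample_list(self):
        samples = disjoint_content_samples()
        model = final_model(samples, k=2, level=5)
        pred, metrics = predict_samples(model, [])
        assert pred.size == 0 and metrics is None

    def test_unlabelled_samples_get_no_metrics(self):
        samples = disjoint_content_samples()
        model = final_model(samples, k=2, level=5)
        new = [ReadSet("x", ["AAAAACAAAAAC"])]
        pred, metrics = predict_samples(model, new)
        assert metrics is None and pred.shape == (1,)

    def test_generalizes_to_fresh_draws_from_same_process(self):
        # Held-out samples from the generating process score close to the
        # LOOCV estimate.
        seeds = (SeedSpec("ACGTAC", 0.05),)
        train, config = tiny_dataset(n_per_class=6, seeds_class2=seeds)
        cv = loocv_cv2(train, k=3)
        level = min(cv.levels)
        model = final_model(train, k=3, level=level)
        accs = []
        for rep in range(10):
            fresh_cfg = SimulationConfig(
                n_per_class=4,
                genome_length=config.genome_length,
                seeds_class2=seeds,
                read_length=50,
                coverage=4.0,
                rng_seed=9000 + rep,
            )
            fresh, _ = generate_dataset(fresh_cfg)
            _, metrics = predict_samples(model, fresh)
            accs.append(metrics["accuracy"])
        assert np.mean(accs) >= cv.accuracies[level] - 0.1
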