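import numpy as np
import pytest

from sisfall.classification import (
    ConfusionCounts,
    ThresholdModel,
    TrialScore,
    UndefinedMetricError,
    classify,
    confusion,
    cross_validate,
    fit_t1,
    fit_t2,
    metrics,
    stratified_kfold,
    transfer_evaluate,
    trial_score,
)
from sisfall.features import FeatureSeries


def scores_from(values, labels, feature="C8"):
    return [
        TrialScore(trial_id=f"t{i}", feature=feature, score=float(v), label=l)
        for i, (v, l) in enumerate(zip(values, labels))
    ]


def brute_force_best_accuracy(values, labels):
    """Independent exhaustive scan: best achievable (SE+SP)/2 by any
    threshold, probing between, below and above all observed scores."""
    values = np.asarray(values, float)
    is_fall = np.asarray([l == "fall" for l in labels])
    probes = np.concatenate([np.unique(values) - 1e-9, [values.max() + 1.0]])
    best = 0.0
    for t in probes:
        pred = values > t
        se = np.sum(pred & is_fall) / is_fall.sum()
        sp = np.sum(~pred & ~is_fall) / (~is_fall).sum()
        best = max(best, (se + sp) / 2)
    return best


class TestTrialScore:
    def test_max_reduction(self):
        series = FeatureSeries("C8", np.array([0.1, 0.9, 0.2]), 0, None)
        assert trial_score(series, "fall", "t0").score == pytest.approx(0.9)

    def test_constant_series(self):
        series = FeatureSeries("C8", np.full(5, 0.7), 0, None)
        assert trial_score(series, "adl", "t0").score == pytest.approx(0.7)

    def test_random_series_matches_python_max(self, rng):
        values = rng.standard_normal(100)
        series = FeatureSeries("C8", values, 0, None)
        assert trial_score(series, "adl", "t0").score == max(values)

    def test_empty_series_rejected(self):
        series = FeatureSeries("C8", np.array([]), 0, None)
        with pytest.raises(ValueError, match="empty"):
            trial_score(series, "adl", "t0")


class TestClassify:
    def test_strict_inequality_and_tie_rule(self):
        model = ThresholdModel("C8", "T1", 0.4)
        assert classify(0.5, model) == "fall"
        assert classify(0.4, model) == "adl"

    def test_feature_mismatch_rejected(self):
        score = TrialScore("t0", "C2", 1.0, "fall")
        with pytest.raises(ValueError, match="mismatch"):
            classify(score, ThresholdModel("C8", "T1", 0.4))

    def test_batch_agrees_with_elementwise(self, rng):
        values = rng.standard_normal(200)
        labels = rng.choice(["fall", "adl"], 200)
        model = ThresholdModel("C8", "T1", 0.1)
        scores = scores_from(values, labels)
        counts = confusion(scores, model)
        manual = [classify(s, model) for s in scores]
        assert counts.tp == sum(
            1 for p, s in zip(manual, scores) if p == "fall" and s.label == "fall"
        )
        assert counts.total == 200


class TestMetrics:
    def test_worked_example(self):
        se, sp, ac = metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert (se, sp, ac) == (0.9, 0.8, pytest.approx(0.85))

    def test_perfect_classifier(self):
        assert metrics(ConfusionCounts(tp=5, fn=0, tn=7, fp=0)) == (1.0, 1.0, 1.0)

    def test_random_counts_match_fraction_oracle(self, rng):
        for _ in range(20):
            tp, fn, tn, fp = rng.integers(1, 50, size=4)
            se, sp, ac = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert se == pytest.approx(tp / (tp + fn))
            assert sp == pytest.approx(tn / (tn + fp))
            assert ac == pytest.approx((se + sp) / 2)

    def test_empty_class_is_an_error_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=0, tn=5, fp=1, fn=0))
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=3, tn=0, fp=0, fn=1))


class TestFitT1:
    def test_separable_midpoint(self):
        scores = scores_from([0, 1, 2, 3], ["adl", "adl", "fall", "fall"])
        model = fit_t1(scores)
        assert model.threshold == pytest.approx(1.5)
        se, sp, ac = metrics(confusion(scores, model))
        assert ac == 1.0

    def test_identical_scores_fall_back_to_sensitivity(self):
        scores = scores_from([1.0] * 6, ["adl", "adl", "adl", "fall", "fall", "fall"])
        model = fit_t1(scores)
        assert model.threshold < 1.0
        se, sp, ac = metrics(confusion(scores, model))
        assert se == 1.0 and ac == pytest.approx(0.5)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 500))
            values = rng.standard_normal(n)
            labels = rng.choice(["fall", "adl"], n)
            if len(set(labels)) < 2:
                continue
            scores = scores_from(values, labels)
            model = fit_t1(scores)
            _, _, ac = metrics(confusion(scores, model))
            assert ac == pytest.approx(brute_force_best_accuracy(values, labels))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            fit_t1(scores_from([1, 2], ["adl", "adl"]))


class TestFitT2:
    def test_just_below_minimum_fall(self):
        scores = scores_from([0, 1, 2.5, 2, 3], ["adl", "adl", "adl", "fall", "fall"])
        model = fit_t2(scores)
        assert model.threshold < 2.0
        se, sp, _ = metrics(confusion(scores, model))
        assert se == 1.0
        assert sp == pytest.approx(2 / 3)

    def test_training_sensitivity_always_one(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 200))
            values = rng.standard_normal(n) * rng.uniform(0.1, 100)
            labels = rng.choice(["fall", "adl"], n)
            if "fall" not in labels:
                continue
            scores = scores_from(values, labels)
            model = fit_t2(scores)
            pred = [classify(s, model) for s in scores]
            assert all(
                p == "fall" for p, s in zip(pred, scores) if s.label == "fall"
            )

    def test_separable_scores_give_perfect_training_metrics(self):
        scores = scores_from([0, 1, 2, 3], ["adl", "adl", "fall", "fall"])
        for fit in (fit_t1, fit_t2):
            _, _, ac = metrics(confusion(scores, fit(scores)))
            assert ac == 1.0

    def test_no_falls_rejected(self):
        with pytest.raises(ValueError):
            fit_t2(scores_from([1, 2], ["adl", "adl"]))


class TestStratifiedKFold:
    def test_exact_proportions_when_divisible(self):
        labels = ["adl"] * 100 + ["fall"] * 50
        folds = stratified_kfold(labels, k=10, seed=0)
        for f in range(10):
            mask = folds == f
            assert sum(mask[:100]) == 10 and sum(mask[100:]) == 5

    def test_within_one_when_not_divisible(self):
        labels = ["adl"] * 101 + ["fall"] * 50
        folds = stratified_kfold(labels, k=10, seed=0)
        sizes = [int(np.sum((folds == f)[:101])) for f in range(10)]
        assert set(sizes) <= {10, 11}

    def test_partition_and_determinism(self):
        labels = ["adl"] * 37 + ["fall"] * 23
        a = stratified_kfold(labels, k=10, seed=5)
        b = stratified_kfold(labels, k=10, seed=5)
        np.testing.assert_array_equal(a, b)
        assert set(a) == set(range(10))
        assert len(a) == 60  # every trial in exactly one fold

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(["adl"] * 50 + ["fall"] * 5, k=10)


class TestCrossValidate:
    def test_separable_scores_are_perfect(self, rng):
        values = np.concatenate([rng.uniform(0, 1, 60), rng.uniform(2, 3, 30)])
        labels = ["adl"] * 60 + ["fall"] * 30
        result = cross_validate(scores_from(values, labels), "T1", k=10, seed=0)
        assert result.ac == (1.0, 0.0)
        assert np.all(result.fold_ac == 1.0)

    def test_accuracy_identity_per_fold(self, rng):
        values = rng.standard_normal(120)
        labels = rng.choice(["fall", "adl"], 120, p=[0.4, 0.6])
        result = cross_validate(scores_from(values, labels), "T1", k=6, seed=1)
        np.testing.assert_allclose(
            result.fold_ac, (result.fold_se + result.fold_sp) / 2, atol=0
        )

    def test_shuffled_labels_near_chance(self, rng):
        values = rng.standard_normal(300)
        labels = rng.permutation(["fall"] * 100 + ["adl"] * 200)
        result = cross_validate(scores_from(values, labels), "T1", k=10, seed=2)
        mean_ac, std_ac = result.ac
        assert abs(mean_ac - 0.5) <= 3 * max(std_ac, 0.02)

    def test_deterministic_given_seed(self, rng):
        values = np.concatenate([rng.standard_normal(60), rng.standard_normal(20) + 1])
        labels = ["adl"] * 60 + ["fall"] * 20
        scores = scores_from(values, labels)
        r1 = cross_validate(scores, "T1", k=5, seed=3)
        r2 = cross_validate(scores, "T1", k=5, seed=3)
        np.testing.assert_array_equal(r1.fold_ac, r2.fold_ac)
        np.testing.assert_array_equal(r1.thresholds, r2.thresholds)

    def test_t2_validation_sensitivity_ordering(self, rng):
        # overlapping classes: T2 sits below T1, so per fold SE(T2) >= SE(T1)
        values = np.concatenate([rng.uniform(0, 2, 100), rng.uniform(1, 3, 50)])
        labels = ["adl"] * 100 + ["fall"] * 50
        scores = scores_from(values, labels)
        t1 = cross_validate(scores, "T1", k=10, seed=4)
        t2 = cross_validate(scores, "T2", k=10, seed=4)
        assert np.all(t2.fold_se >= t1.fold_se)
        assert np.all(t2.fold_sp <= t1.fold_sp)

    def test_small_class_rejected(self):
        scores = scores_from([1, 2, 3, 4], ["fall", "adl", "adl", "adl"])
        with pytest.raises(ValueError):
            cross_validate(scores, "T1", k=4)


class TestTransferEvaluate:
    def test_identity_transfer_equals_training_metrics(self, rng):
        values = rng.standard_normal(100)
        labels = rng.choice(["fall", "adl"], 100)
        scores = scores_from(values, labels)
        result = transfer_evaluate(scores, scores, "T1")
        model = fit_t1(scores)
        se, sp, ac = metrics(confusion(scores, model))
        assert result.fold_se[0] == se and result.fold_sp[0] == sp

    def test_shrunk_test_scores_lose_sensitivity(self, rng):
        values = np.concatenate([rng.uniform(0, 1, 60), rng.uniform(1.5, 3, 40)])
        labels = ["adl"] * 60 + ["fall"] * 40
        train = scores_from(values, labels)
        shrunk = scores_from(0.7 * values, labels)
        r_train = transfer_evaluate(train, train, "T1")
        r_shrunk = transfer_evaluate(train, shrunk, "T1")
        assert r_shrunk.fold_se[0] <= r_train.fold_se[0]

    def test_empty_test_rejected(self):
        train = scores_from([0, 1, 2, 3], ["adl", "adl", "fall", "fall"])
        with pytest.raises(ValueError):
            transfer_evaluate(train, [], "T1")

    def test_summary_format(self):
        train = scores_from([0, 1, 2, 3], ["adl", "adl", "fall", "fall"])
        result = transfer_evaluate(train, train, "T1")
        assert "SE 100.00" in result.summary() and "±" in result.summary()
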