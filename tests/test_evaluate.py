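import numpy as np
import pytest
from scipy import stats
from scipy.special import comb
from sklearn.metrics import roc_auc_score

from stemsvm.evaluate import (
    ConfusionCounts,
    auc_trapezoid,
    confusion_metrics,
    fisher_overlap,
    loocv,
    rank_correlation,
    roc_points,
    roc_threefold,
)
from stemsvm.kernels import KernelSpec, compute_kernel

# printed accuracy and signal-to-noise columns of the 21 evaluated
# configurations, as published
TABLE2_ACC = [0.82, 0.73, 0.90, 0.84, 0.87, 0.87, 0.87, 0.84, 0.90, 0.86, 0.88,
              0.91, 0.88, 0.85, 0.92, 0.86, 0.90, 0.94, 0.88, 0.83, 0.93]
TABLE3_RATIO = [1.44, 1.00, 3.91, 1.36, 1.84, 1.88, 1.57, 1.86, 1.91, 1.80, 1.96,
                3.82, 1.84, 1.65, 2.35, 1.80, 3.43, 3.80, 1.84, 1.38, 3.21]


class TestConfusionMetrics:
    def test_expression_rbf_row(self):
        m = confusion_metrics(ConfusionCounts(tp=37, fp=3, tn=67, fn=9))
        assert m.accuracy == pytest.approx(104 / 116)
        assert round(m.accuracy, 2) == 0.90
        assert round(m.tpr, 2) == 0.80
        assert round(m.fpr, 2) == 0.04

    def test_weighted_continuous_rbf_row(self):
        m = confusion_metrics(ConfusionCounts(tp=42, fp=5, tn=65, fn=4))
        assert round(m.accuracy, 2) == 0.92
        assert round(m.tpr, 2) == 0.91
        assert round(m.fpr, 2) == 0.07

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fp=0, tn=12, fn=0))
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_f1_hand_computation(self):
        m = confusion_metrics(ConfusionCounts(tp=42, fp=5, tn=0, fn=4))
        assert m.f1 == pytest.approx(84 / 93)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_undefined_components_are_none(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.precision is None and m.tpr is None
        assert m.fpr == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


def _rbf_K(X, sigma=2.0):
    return compute_kernel(X, X, KernelSpec("rbf", sigma=sigma))


class TestLoocv:
    def test_perfect_on_separable(self, separable_xy):
        X, y = separable_xy
        res = loocv([("rbf", _rbf_K(X))], y)
        assert res.accuracy == 1.0
        assert res.confusion.tp + res.confusion.fn == int(np.sum(y == 1))

    def test_iteration_count_equals_n(self, separable_xy):
        X, y = separable_xy
        res = loocv([("rbf", _rbf_K(X))], y)
        assert len(res.predictions) == len(y)

    def test_confusion_totals_match_class_sizes(self, small_dataset):
        y = small_dataset["y"]
        res = loocv([("rbf", _rbf_K(small_dataset["Xm"]))], y)
        assert res.confusion.tp + res.confusion.fn == int(np.sum(y == 1))
        assert res.confusion.tn + res.confusion.fp == int(np.sum(y == -1))

    def test_null_features_near_majority_accuracy(self):
        """Random features: mean LOOCV accuracy ~ majority-class fraction."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 8))
            y = np.array([1] * 8 + [-1] * 12)
            accs.append(loocv([("rbf", _rbf_K(X))], y).accuracy)
        assert abs(np.mean(accs) - 12 / 20) <= 0.10

    def test_nested_selection_runs_and_orders_ties_small_sigma_first(self, separable_xy):
        X, y = separable_xy
        cands = [(f"s={s}", _rbf_K(X, s)) for s in (0.5, 1.0, 2.0)]
        res = loocv(cands, y, nested=True)
        assert res.accuracy == 1.0
        # ties across candidates resolve to the earliest (smallest sigma)
        assert res.predictions["chosen"].iloc[0] == "s=0.5"

    def test_flat_selection(self, separable_xy):
        X, y = separable_xy
        cands = [(f"s={s}", _rbf_K(X, s)) for s in (0.5, 2.0)]
        res = loocv(cands, y, nested=False)
        assert res.predictions["chosen"].nunique() == 1

    def test_class_starvation_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        y = np.array([1, 1, -1, -1, -1, -1])
        with pytest.raises(ValueError):
            loocv([("rbf", _rbf_K(X))], np.array([1, -1, -1, -1, -1, -1]))
        assert loocv([("rbf", _rbf_K(X))], y).confusion.total == 6

    def test_accuracy_equals_mean_correctness(self, small_dataset):
        res = loocv([("rbf", _rbf_K(small_dataset["Xm"]))], small_dataset["y"])
        manual = np.mean(res.predictions["true"] == res.predictions["predicted"])
        assert res.accuracy == pytest.approx(manual)


class TestROC:
    def test_perfect_ranking_auc_one(self):
        y = np.array([1, 1, 1, -1, -1, -1])
        fpr, tpr = roc_points(np.array([3.0, 2.5, 2.0, 1.0, 0.5, 0.1]), y)
        assert auc_trapezoid(fpr, tpr) == 1.0

    def test_anti_ranking_auc_zero(self):
        y = np.array([1, 1, -1, -1])
        fpr, tpr = roc_points(np.array([0.1, 0.2, 0.9, 1.0]), y)
        assert auc_trapezoid(fpr, tpr) == 0.0

    def test_random_scores_auc_half(self):
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = np.array([1] * 10 + [-1] * 10)
            fpr, tpr = roc_points(rng.normal(size=20), y)
            aucs.append(auc_trapezoid(fpr, tpr))
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_curves_monotone(self):
        rng = np.random.default_rng(3)
        y = np.where(rng.random(30) > 0.5, 1, -1)
        y[:2] = [1, -1]
        fpr, tpr = roc_points(rng.normal(size=30), y)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_auc_matches_sklearn_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            y = np.where(rng.random(40) > 0.4, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.normal(size=40) + 0.5 * y
            fpr, tpr = roc_points(scores, y)
            assert auc_trapezoid(fpr, tpr) == pytest.approx(
                roc_auc_score(y, scores)
            )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        y = np.array([1] * 15 + [-1] * 15)
        scores = rng.normal(size=30) + y
        base = auc_trapezoid(*roc_points(scores, y))
        for f in (np.exp, np.tanh, lambda s: 3 * s - 7):
            assert auc_trapezoid(*roc_points(f(scores), y)) == pytest.approx(base)

    def test_threefold_structure(self, small_dataset):
        y = small_dataset["y"]
        res = roc_threefold(_rbf_K(small_dataset["Xm"]), y, seed=1)
        assert len(res.folds) == 3
        assert 0.0 <= res.auc_mean <= 1.0
        covered = np.concatenate([f["test_index"] for f in res.folds])
        assert sorted(covered) == list(range(len(y)))

    def test_threefold_seed_determinism(self, small_dataset):
        K, y = _rbf_K(small_dataset["Xm"]), small_dataset["y"]
        a = roc_threefold(K, y, seed=2)
        b = roc_threefold(K, y, seed=2)
        assert a.auc_mean == b.auc_mean

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            roc_threefold(np.eye(4), np.array([1, 1, -1, -1]))


class TestRankCorrelation:
    def test_identical_rankings(self):
        assert rank_correlation([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        assert rank_correlation([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(6)
        u = rng.integers(0, 5, size=30).astype(float)
        v = u + rng.integers(0, 3, size=30)
        expected = stats.spearmanr(u, v).statistic
        assert rank_correlation(u, v) == pytest.approx(expected)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1.0, 2.0], [2.0, 1.0])

    def test_printed_accuracy_vs_ratio_columns(self):
        # ~0.88 without tie correction; 0.89 reported
        rho = rank_correlation(TABLE2_ACC, TABLE3_RATIO)
        assert 0.87 <= rho <= 0.90
        assert rho == pytest.approx(0.8814, abs=1e-3)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        u, v = rng.normal(size=15), rng.normal(size=15)
        base = rank_correlation(u, v)
        assert rank_correlation(np.exp(u), v**3) == pytest.approx(base)


def _brute_force_hypergeom_tail(k, N, K, n):
    """P(overlap >= k) by exhaustive summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
    return total / comb(N, n, exact=True)


class TestFisherOverlap:
    def test_disjoint_singletons_near_one(self):
        p = fisher_overlap(["a"], ["b"], 1000)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_identical_lists_closed_form(self):
        genes = [f"g{i}" for i in range(10)]
        p = fisher_overlap(genes, genes, 100)
        assert p == pytest.approx(1.0 / comb(100, 10, exact=True), rel=1e-9)

    def test_matches_brute_force_oracle(self):
        listA = [f"g{i}" for i in range(10)]
        listB = [f"g{i}" for i in range(5, 15)]  # overlap 5, sizes 10/10
        p = fisher_overlap(listA, listB, 100)
        assert p == pytest.approx(_brute_force_hypergeom_tail(5, 100, 10, 10), rel=1e-9)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(["a", "b"], ["c", "d"], 3)
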