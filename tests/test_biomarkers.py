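"""Biomarker panel selection: RF elimination, subsets, LOOCV SVM, AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from cerna_net import (
    enumerate_subsets,
    loocv_svm,
    rf_iterative_selection,
    roc_auc,
    select_optimal_panel,
)

from conftest import make_labels


def _feature_frame(x: np.ndarray, prefix="F") -> pd.DataFrame:
    return pd.DataFrame(
        x,
        index=[f"{prefix}{i:02d}" for i in range(x.shape[0])],
        columns=[f"S{j}" for j in range(x.shape[1])],
    )


def _noise_problem(rng, n_features, n0, n1, informative=(), shift=3.0):
    x = rng.standard_normal((n_features, n0 + n1))
    for i in informative:
        x[i, n0:] += shift
    return _feature_frame(x), make_labels(n0, n1)


class TestSubsets:
    @pytest.mark.parametrize("k,expected", [(7, 127), (6, 63), (1, 1)])
    def test_cardinality(self, k, expected):
        subs = enumerate_subsets([f"F{i}" for i in range(k)])
        assert len(subs) == expected
        assert len(set(subs)) == expected

    def test_ordering_by_size_then_lexicographic(self):
        subs = enumerate_subsets(["b", "a", "c"])
        assert subs == [
            ("a",), ("b",), ("c",),
            ("a", "b"), ("a", "c"), ("b", "c"),
            ("a", "b", "c"),
        ]

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError):
            enumerate_subsets([f"F{i}" for i in range(21)])
        with pytest.raises(ValueError):
            enumerate_subsets([])


class TestRfElimination:
    def test_discard_arithmetic_16_to_6(self):
        rng = np.random.default_rng(0)
        x, labels = _noise_problem(rng, 16, 10, 10)
        trace = rf_iterative_selection(x, labels, target_k=7, seed=1, n_trees=25)
        sizes = [len(it["retained"]) for it in trace.iterations]
        # 16 -> 11 -> 8 -> 6: each step discards max(1, floor(k/3))
        assert sizes == [11, 8, 6]
        assert len(trace.retained) == 6

    def test_nine_features_one_step(self):
        rng = np.random.default_rng(1)
        x, labels = _noise_problem(rng, 9, 8, 8)
        trace = rf_iterative_selection(x, labels, target_k=6, seed=1, n_trees=25)
        assert len(trace.iterations[0]["retained"]) == 6

    def test_nested_retained_sets(self):
        rng = np.random.default_rng(2)
        x, labels = _noise_problem(rng, 16, 10, 10)
        trace = rf_iterative_selection(x, labels, target_k=4, seed=3, n_trees=25)
        prev = set(x.index)
        for it in trace.iterations:
            cur = set(it["retained"])
            assert cur < prev
            prev = cur

    def test_target_at_least_initial_is_trivial(self):
        rng = np.random.default_rng(3)
        x, labels = _noise_problem(rng, 5, 6, 6)
        trace = rf_iterative_selection(x, labels, target_k=5, seed=1)
        assert len(trace.iterations) == 1
        assert trace.retained == list(x.index)

    def test_informative_feature_survives(self):
        kept = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x, labels = _noise_problem(rng, 16, 12, 12, informative=(0,), shift=3.0)
            trace = rf_iterative_selection(x, labels, target_k=5, seed=seed, n_trees=60)
            kept += "F00" in trace.retained
        assert kept >= 19  # >= 95% of seeds

    def test_determinism(self):
        rng = np.random.default_rng(4)
        x, labels = _noise_problem(rng, 10, 8, 8)
        a = rf_iterative_selection(x, labels, target_k=4, seed=9, n_trees=30)
        b = rf_iterative_selection(x, labels, target_k=4, seed=9, n_trees=30)
        assert a.retained == b.retained
        assert a.iterations[0]["importance"] == b.iterations[0]["importance"]


class TestAuc:
    def test_scores_equal_labels(self):
        assert roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_reversed_scores(self):
        assert roc_auc([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_all_ties_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    @given(st.integers(0, 500))
    def test_equals_pairwise_probability_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        scores = np.round(rng.standard_normal(n), 1)  # rounding makes ties
        auc = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairwise = np.mean(
            (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        )
        assert auc == pytest.approx(pairwise, abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestLoocv:
    def test_separable_problem_is_perfect(self):
        rng = np.random.default_rng(5)
        x, labels = _noise_problem(rng, 1, 10, 10, informative=(0,), shift=10.0)
        r = loocv_svm(x, labels)
        assert r.accuracy == 1.0
        assert r.auc == 1.0
        assert r.confusion == {"tp": 10, "fp": 0, "tn": 10, "fn": 0}

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        x, labels = _noise_problem(rng, 3, 8, 8, informative=(0,), shift=1.0)
        r1 = loocv_svm(x, labels)
        perm = rng.permutation(x.shape[1])
        x2 = x.iloc[:, perm]
        r2 = loocv_svm(x2, labels.iloc[perm])
        assert r1.accuracy == r2.accuracy
        # decision values agree to solver tolerance regardless of order
        np.testing.assert_allclose(
            r1.scores.sort_index(), r2.scores.sort_index(), atol=1e-4
        )

    def test_determinism(self):
        rng = np.random.default_rng(7)
        x, labels = _noise_problem(rng, 2, 6, 6)
        a = loocv_svm(x, labels)
        b = loocv_svm(x, labels)
        assert a.accuracy == b.accuracy and a.auc == b.auc
        assert a.scores.equals(b.scores)

    def test_null_accuracy_is_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            x, labels = _noise_problem(rng, 4, 15, 15)
            accs.append(loocv_svm(x, labels).accuracy)
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_minimum_samples(self):
        rng = np.random.default_rng(8)
        x, labels = _noise_problem(rng, 2, 1, 2)
        with pytest.raises(ValueError, match="4 samples"):
            loocv_svm(x, labels)

    def test_singleton_class_fold_flagged(self):
        rng = np.random.default_rng(9)
        x, labels = _noise_problem(rng, 2, 1, 5)
        r = loocv_svm(x, labels)
        # the fold holding out the lone class-0 sample trains one-class
        assert r.degenerate_folds == 1


class TestOptimalPanel:
    def test_separating_feature_wins(self):
        rng = np.random.default_rng(10)
        x, labels = _noise_problem(rng, 4, 10, 10, informative=(0,), shift=10.0)
        best, ranked, trace = select_optimal_panel(x, labels, target_k=4, seed=0)
        assert "F00" in best.features
        assert best.accuracy == 1.0
        assert len(ranked) == 2**4 - 1

    def test_six_retained_gives_63_rows(self):
        rng = np.random.default_rng(11)
        x, labels = _noise_problem(rng, 9, 8, 8)
        best, ranked, trace = select_optimal_panel(
            x, labels, target_k=6, seed=1, n_trees=25
        )
        assert len(trace.retained) == 6
        assert len(ranked) == 63

    def test_null_accuracy_not_above_permutation(self):
        # optimal-subset accuracy on pure noise, compared with the same
        # search under label permutation: observed must not exceed the
        # permutation distribution significantly
        rng = np.random.default_rng(12)
        x, labels = _noise_problem(rng, 5, 8, 8)
        best, _, _ = select_optimal_panel(x, labels, target_k=3, seed=0, n_trees=25)
        perm_accs = []
        for i in range(12):
            perm = rng.permutation(len(labels))
            pl = pd.Series(labels.to_numpy()[perm], index=labels.index)
            b, _, _ = select_optimal_panel(x, pl, target_k=3, seed=0, n_trees=25)
            perm_accs.append(b.accuracy)
        # one-sided permutation check at ~0.1 level
        exceed = sum(a >= best.accuracy for a in perm_accs)
        assert exceed >= 1
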