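"""Multi-label measure tests against hand-enumerated and naive oracles."""

import math

import numpy as np
import pytest
from helpers_naive import all_binary_matrices, naive_metrics

from rnalocmkl import metrics
from rnalocmkl.metrics import evaluate, rank_labels, ranking_metrics, set_metrics
from rnalocmkl.synthetic import generate_worked_example


class TestRankLabels:
    def test_strictly_ordered(self):
        assert rank_labels(np.array([[0.9, 0.8, 0.1]])).tolist() == [[1, 2, 3]]

    def test_ties_broken_by_index(self):
        assert rank_labels(np.array([[0.5, 0.5]])).tolist() == [[1, 2]]

    def test_column_reversal_permutes_ranks_consistently(self, rng):
        s = rng.random((1, 6))  # continuous draws: distinct a.s.
        forward = rank_labels(s)[0]
        backward = rank_labels(s[:, ::-1].copy())[0]
        assert np.array_equal(backward[::-1], forward)

    def test_rank_is_permutation(self, rng):
        ranks = rank_labels(rng.random((5, 4)))
        for row in ranks:
            assert sorted(row) == [1, 2, 3, 4]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rank_labels(np.array([[np.nan, 0.0]]))


class TestWorkedExample:
    def test_all_six_values(self):
        Y, scores, yhat, expected = generate_worked_example()
        report = evaluate(Y, scores, yhat)
        for name, value in expected.items():
            assert getattr(report, name) == pytest.approx(value), name


class TestRankingMetrics:
    def test_perfect_ranking(self):
        Y = np.array([[1, 1, 0, 0], [1, 0, 0, 0]])
        scores = np.array([[0.9, 0.8, 0.2, 0.1], [0.9, 0.1, 0.2, 0.3]])
        out = ranking_metrics(Y, scores)
        assert out["average_precision"] == 1.0
        assert out["ranking_loss"] == 0.0
        assert out["one_error"] == 0.0
        assert out["coverage"] == pytest.approx((1 + 0) / 2)  # |Y_i| - 1 each

    def test_all_labels_positive_degenerate(self):
        Y = np.array([[1, 1, 1]])
        scores = np.array([[0.2, 0.5, 0.9]])
        out = ranking_metrics(Y, scores)
        assert out["coverage"] == 2  # L - 1
        assert math.isnan(out["ranking_loss"])  # no negative label

    def test_no_qualifying_rows_gives_nan_not_zero(self):
        Y = np.zeros((2, 3), dtype=int)
        out = ranking_metrics(Y, np.random.default_rng(0).random((2, 3)))
        assert math.isnan(out["average_precision"])
        assert math.isnan(out["coverage"])

    def test_ties_count_as_ranking_losses(self):
        Y = np.array([[1, 0]])
        scores = np.array([[0.5, 0.5]])
        assert ranking_metrics(Y, scores)["ranking_loss"] == 1.0


class TestSetMetrics:
    def test_hand_computed_overlap(self):
        # truth {1,3}, prediction {1,2}, L=3
        Y = np.array([[1, 0, 1]])
        yhat = np.array([[1, 1, 0]])
        out = set_metrics(Y, yhat)
        assert out["accuracy"] == pytest.approx(1 / 3)
        assert out["hamming_loss"] == pytest.approx(2 / 3)

    def test_identity(self, rng):
        Y = rng.integers(0, 2, size=(6, 4))
        out = set_metrics(Y, Y)
        assert out["accuracy"] == 1.0
        assert out["hamming_loss"] == 0.0

    def test_disjoint_singletons(self):
        Y = np.array([[1, 0, 0, 0]])
        yhat = np.array([[0, 1, 0, 0]])
        out = set_metrics(Y, yhat)
        assert out["accuracy"] == 0.0
        assert out["hamming_loss"] == pytest.approx(0.5)

    def test_empty_vs_empty_counts_as_agreement(self):
        out = set_metrics(np.array([[0, 0]]), np.array([[0, 0]]))
        assert out["accuracy"] == 1.0


class TestNaiveOracleEquivalence:
    @pytest.mark.parametrize("n,L", [(1, 2), (2, 2), (2, 3), (3, 2)])
    def test_exhaustive_small(self, n, L):
        rng = np.random.default_rng(n * 10 + L)
        for Y in all_binary_matrices(n, L):
            scores = rng.random((n, L))
            yhat = (scores >= 0.5).astype(int)
            mine = evaluate(Y, scores, yhat).as_dict()
            ref = naive_metrics(Y, scores, yhat)
            for name in metrics.METRIC_NAMES:
                if math.isnan(ref[name]):
                    assert math.isnan(mine[name]), name
                else:
                    assert mine[name] == pytest.approx(ref[name]), name

    def test_random_larger_instances_with_ties(self, rng):
        for _ in range(30):
            n, L = rng.integers(2, 8), rng.integers(2, 6)
            Y = rng.integers(0, 2, size=(n, L))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=(n, L))  # forces ties
            yhat = rng.integers(0, 2, size=(n, L))
            mine = evaluate(Y, scores, yhat).as_dict()
            ref = naive_metrics(Y, scores, yhat)
            for name in metrics.METRIC_NAMES:
                assert mine[name] == pytest.approx(ref[name]) or (
                    math.isnan(mine[name]) and math.isnan(ref[name])
                ), name


class TestSklearnCrossCheck:
    """Tie-free random instances compared against scikit-learn's measures."""

    def test_ranking_measures(self, rng):
        from sklearn.metrics import (
            coverage_error,
            hamming_loss,
            label_ranking_average_precision_score,
            label_ranking_loss,
        )

        for _ in range(10):
            n, L = 8, 5
            Y = rng.integers(0, 2, size=(n, L))
            # every row needs a positive and a negative so that both
            # implementations average over the same rows
            Y[Y.sum(axis=1) == 0, 0] = 1
            Y[Y.sum(axis=1) == L, 0] = 0
            scores = rng.random((n, L))  # continuous: ties a.s. absent
            out = ranking_metrics(Y, scores)
            assert out["average_precision"] == pytest.approx(
                label_ranking_average_precision_score(Y, scores)
            )
            assert out["coverage"] == pytest.approx(coverage_error(Y, scores) - 1)
            assert out["ranking_loss"] == pytest.approx(label_ranking_loss(Y, scores))
            yhat = rng.integers(0, 2, size=(n, L))
            assert set_metrics(Y, yhat)["hamming_loss"] == pytest.approx(
                hamming_loss(Y, yhat)
            )


class TestMonotonicity:
    def test_raising_a_positive_score_never_hurts(self, rng):
        """Pushing a true label's score up can only improve AP and
        ranking loss (smaller), matching the better-is-larger/smaller
        orientation of the measures."""
        for _ in range(100):
            n, L = 4, 5
            Y = rng.integers(0, 2, size=(n, L))
            Y[Y.sum(axis=1) == 0, 0] = 1
            scores = rng.random((n, L))
            before = ranking_metrics(Y, scores)
            i = int(rng.integers(n))
            pos = np.flatnonzero(Y[i])
            j = int(rng.choice(pos))
            bumped = scores.copy()
            bumped[i, j] = min(1.0, bumped[i, j] + rng.uniform(0, 1))
            after = ranking_metrics(Y, bumped)
            assert after["average_precision"] >= before["average_precision"] - 1e-12
            if not math.isnan(before["ranking_loss"]):
                assert after["ranking_loss"] <= before["ranking_loss"] + 1e-12
            assert after["coverage"] <= before["coverage"] + 1e-12

    def test_ap_one_iff_positives_on_top(self, rng):
        for _ in range(50):
            L = 5
            Y = rng.integers(0, 2, size=(1, L))
            Y[0, 0] = 1
            scores = rng.random((1, L))
            out = ranking_metrics(Y, scores)
            ranks = rank_labels(scores)[0]
            k = Y.sum()
            on_top = set(np.flatnonzero(Y[0])) == set(np.argsort(ranks)[:k])
            assert (out["average_precision"] == 1.0) == on_top
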