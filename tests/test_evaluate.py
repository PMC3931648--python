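"""Discard-aware confusion semantics, metrics, sweeps and Spearman."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from accelknn.evaluate import (
    DEFAULT_THRESHOLDS,
    ConfusionCounts,
    accuracy,
    apply_threshold,
    confusion_counts,
    metrics_report,
    per_behavior_counts,
    precision,
    recall,
    spearman,
    sweep,
)

from conftest import make_vote


def literal_confusion(pairs, threshold):
    """Oracle: if/else transcription of the four-way assignment."""
    tp = fp = tn = fn = 0
    for correct, prob in pairs:
        if prob >= threshold and correct:
            tp += 1
        elif prob >= threshold and not correct:
            fp += 1
        elif prob < threshold and not correct:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def votes_from_pairs(pairs):
    """(correct, prob) pairs -> votes predicting 'A', truths 'A' or 'B'."""
    votes = [make_vote("A", prob, i) for i, (_, prob) in enumerate(pairs)]
    truths = ["A" if correct else "B" for correct, _ in pairs]
    return votes, truths


def random_pairs(rng, n=200):
    # probs on the k=5 grid plus exact boundary values
    grid = [0.2, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    return [(bool(rng.integers(2)), grid[rng.integers(len(grid))]) for _ in range(n)]


class TestConfusionCounts:
    def test_one_sample_per_cell(self):
        votes, truths = votes_from_pairs(
            [(True, 0.9), (False, 0.9), (False, 0.4), (True, 0.4)]
        )
        c = confusion_counts(votes, truths, 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_threshold_zero_discards_nothing(self, rng):
        votes, truths = votes_from_pairs(random_pairs(rng, 50))
        c = confusion_counts(votes, truths, 0.0)
        assert c.tn == 0 and c.fn == 0
        assert c.tp + c.fp == 50

    def test_matches_literal_if_else_oracle(self, rng):
        pairs = random_pairs(rng)
        votes, truths = votes_from_pairs(pairs)
        for thr in DEFAULT_THRESHOLDS:
            c = confusion_counts(votes, truths, thr)
            assert (c.tp, c.fp, c.tn, c.fn) == literal_confusion(pairs, thr)

    def test_boundary_prob_equal_to_threshold_is_kept(self):
        votes, truths = votes_from_pairs([(True, 0.7)])
        c = confusion_counts(votes, truths, 0.7)
        assert c.tp == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([make_vote("A", 1.0)], ["A", "B"], 0.5)

    @settings(max_examples=50, deadline=None)
    @given(
        pairs=st.lists(
            st.tuples(st.booleans(), st.sampled_from([0.2, 0.4, 0.6, 0.8, 1.0])),
            min_size=1,
            max_size=60,
        ),
        thr=st.sampled_from([0.0, 0.3, 0.5, 0.7, 0.9, 1.0]),
    )
    def test_cells_partition_the_test_set(self, pairs, thr):
        votes, truths = votes_from_pairs(pairs)
        c = confusion_counts(votes, truths, thr)
        assert c.total == len(pairs)

    @settings(max_examples=50, deadline=None)
    @given(
        pairs=st.lists(
            st.tuples(st.booleans(), st.sampled_from([0.2, 0.4, 0.6, 0.8, 1.0])),
            min_size=1,
            max_size=60,
        )
    )
    def test_conservation_across_thresholds(self, pairs):
        votes, truths = votes_from_pairs(pairs)
        quads = [confusion_counts(votes, truths, t) for t in DEFAULT_THRESHOLDS]
        assert len({(c.tp + c.fn) for c in quads}) == 1
        assert len({(c.fp + c.tn) for c in quads}) == 1


class TestMetrics:
    def test_textbook_values(self):
        assert accuracy(ConfusionCounts(1, 1, 1, 1)) == 0.5
        assert accuracy(ConfusionCounts(7, 0, 0, 0)) == 1.0
        assert precision(ConfusionCounts(3, 1, 0, 0)) == 0.75
        assert recall(ConfusionCounts(4, 0, 0, 1)) == 0.8

    def test_zero_denominators_are_explicit_not_a_value(self):
        assert precision(ConfusionCounts(0, 0, 5, 5)) is None
        assert recall(ConfusionCounts(0, 5, 5, 0)) is None

    def test_random_counts_match_ratio_oracle(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 20, size=4))
            if tp + fp + tn + fn == 0:
                continue
            c = ConfusionCounts(tp, fp, tn, fn)
            assert accuracy(c) == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            if tp + fp:
                assert precision(c) == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert recall(c) == pytest.approx(tp / (tp + fn))


class TestSweep:
    def test_all_unanimous_and_correct_gives_perfect_reports(self):
        votes = [make_vote("A", 1.0, i) for i in range(10)]
        res = sweep(votes, ["A"] * 10)
        for rep in res.reports:
            assert rep.accuracy == rep.precision == rep.recall == 1.0
            assert rep.proportion_classified == 1.0
        # constant metrics have zero rank variance
        assert res.correlations["accuracy"].r is None

    def test_hand_built_fixture_matches_per_metric_recomputation(self):
        pairs = [(True, 1.0), (True, 0.8), (False, 0.8), (True, 0.6),
                 (False, 0.6), (True, 0.55), (False, 0.4), (True, 0.4),
                 (False, 1.0), (True, 0.9)]
        votes, truths = votes_from_pairs(pairs)
        res = sweep(votes, truths)
        for rep in res.reports:
            tp, fp, tn, fn = literal_confusion(pairs, rep.threshold)
            n = len(pairs)
            assert (rep.counts.tp, rep.counts.fp, rep.counts.tn, rep.counts.fn) == (
                tp, fp, tn, fn)
            assert rep.accuracy == pytest.approx((tp + tn) / n)
            assert rep.proportion_classified == pytest.approx((tp + fp) / n)

    def test_metric_identities_at_threshold_zero(self, rng):
        pairs = random_pairs(rng, 100)
        votes, truths = votes_from_pairs(pairs)
        rep = metrics_report(votes, truths, 0.0)
        assert rep.accuracy == rep.precision
        if rep.counts.tp > 0:
            assert rep.recall == 1.0

    def test_proportion_classified_and_recall_non_increasing(self, rng):
        pairs = random_pairs(rng, 150)
        votes, truths = votes_from_pairs(pairs)
        res = sweep(votes, truths, (0.0, 0.2, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0))
        props = [r.proportion_classified for r in res.reports]
        assert all(b <= a for a, b in zip(props, props[1:]))
        recs = [r.recall for r in res.reports if r.recall is not None]
        assert all(b <= a for a, b in zip(recs, recs[1:]))

    def test_non_increasing_thresholds_rejected(self):
        votes = [make_vote("A", 1.0)]
        with pytest.raises(ValueError):
            sweep(votes, ["A"], (0.5, 0.5))


class TestPerBehaviorDiagnostics:
    def test_one_vs_rest_partition(self):
        votes = [make_vote(p, 1.0, i) for i, p in enumerate("AABB")]
        truths = list("ABAB")
        c = per_behavior_counts(votes, truths, 0.5, "A")
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
        assert c.total == 4


class TestSpearman:
    def test_perfect_monotone_fixtures(self):
        up = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        down = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert up.r == pytest.approx(1.0)
        assert down.r == pytest.approx(-1.0)
        # only the identity and the full reversal reach |r| = 1
        assert up.p == pytest.approx(2 / math.factorial(5))

    def test_constant_input_signalled_undefined(self):
        res = spearman([1, 2, 3, 4], [7, 7, 7, 7])
        assert res.r is None and res.p is None

    def test_r_matches_rank_then_pearson_reference(self, rng):
        for _ in range(30):
            xs = rng.normal(size=5)
            ys = rng.normal(size=5)
            res = spearman(xs, ys)
            rx, ry = stats.rankdata(xs), stats.rankdata(ys)
            expect = np.corrcoef(rx, ry)[0, 1]
            assert res.r == pytest.approx(expect, abs=1e-12)

    def test_exact_p_matches_full_permutation_enumeration(self, rng):
        for _ in range(10):
            xs = rng.normal(size=5)
            ys = rng.normal(size=5)
            res = spearman(xs, ys)
            rx, ry = stats.rankdata(xs), stats.rankdata(ys)
            robs = abs(np.corrcoef(rx, ry)[0, 1])
            count = 0
            for perm in permutations(ry):
                if abs(np.corrcoef(rx, perm)[0, 1]) >= robs - 1e-12:
                    count += 1
            assert res.p == pytest.approx(count / math.factorial(5))

    def test_ties_use_average_ranks_like_scipy(self, rng):
        xs = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        ys = [3.0, 3.0, 5.0, 1.0, 4.0, 4.0]
        assert spearman(xs, ys).r == pytest.approx(stats.spearmanr(xs, ys).statistic)

    def test_large_n_uses_t_approximation_like_scipy(self, rng):
        xs = rng.normal(size=25)
        ys = xs + rng.normal(size=25)
        res = spearman(xs, ys)
        ref = stats.spearmanr(xs, ys)
        assert res.r == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_spearman_of_x_with_itself_and_negation(self, rng):
        xs = rng.permutation(np.arange(8)).astype(float)
        assert spearman(xs, xs).r == pytest.approx(1.0)
        assert spearman(xs, -xs).r == pytest.approx(-1.0)


class TestApplyThreshold:
    def test_flags_without_dropping(self):
        votes = [make_vote("A", 0.4), make_vote("B", 0.9)]
        cls = apply_threshold(votes, 0.5, truths=["A", "A"])
        assert len(cls) == 2
        assert [c.passed for c in cls] == [False, True]
        assert cls[1].true_label == "A"
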