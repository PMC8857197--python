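"""Gold-standard evaluation: AUPR/AUROC, set scores, Simpson index."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from grnkit.assess import (
    RankedPredictions,
    gold_universe_size,
    gr_prediction_scores,
    pr_curve,
    restrict_to_gold,
    roc_curve,
    simpson_index,
)
from grnkit.core import GRNError
from conftest import make_grn


def ranking(pairs_scores, label="m"):
    return RankedPredictions.from_scores(
        [(r, t, s) for (r, t), s in pairs_scores], method_label=label
    )


def brute_force_aupr(labels, n_pos):
    """Pointwise PR enumeration over prefixes (no ties), trapezoid area."""
    tp = fp = 0
    recalls, precisions = [0.0], []
    for is_pos in labels:
        tp += is_pos
        fp += 1 - is_pos
        recalls.append(tp / n_pos)
        precisions.append(tp / (tp + fp))
    precisions = [precisions[0]] + precisions
    return float(np.trapezoid(precisions, recalls))


class TestRankedPredictions:
    def test_duplicate_pair_rejected(self):
        with pytest.raises(GRNError):
            RankedPredictions([("A", "B", 2.0), ("A", "B", 1.0)])

    def test_increasing_scores_rejected(self):
        with pytest.raises(GRNError):
            RankedPredictions([("A", "B", 1.0), ("A", "C", 2.0)])

    def test_from_scores_sorts_with_lexicographic_ties(self):
        rp = RankedPredictions.from_scores(
            [("B", "X", 1.0), ("A", "X", 1.0), ("C", "X", 2.0)]
        )
        assert rp.pairs() == [("C", "X"), ("A", "X"), ("B", "X")]

    def test_tie_groups(self):
        rp = RankedPredictions([("A", "B", 2.0), ("A", "C", 1.0), ("B", "C", 1.0)])
        assert [len(g) for g in rp.tie_groups()] == [1, 2]


class TestRestrictToGold:
    def test_identity_when_all_endpoints_known(self):
        gold = make_grn([("A", "B"), ("B", "C")])
        rp = ranking([(("A", "B"), 2.0), (("B", "C"), 1.0)])
        assert restrict_to_gold(rp, gold).pairs() == rp.pairs()

    def test_unknown_endpoint_dropped_order_preserved(self):
        gold = make_grn([("A", "B")])
        rp = ranking([(("A", "B"), 3.0), (("A", "Q"), 2.0), (("B", "A"), 1.0)])
        assert restrict_to_gold(rp, gold).pairs() == [("A", "B"), ("B", "A")]

    def test_empty_gold_empties_predictions(self):
        gold = make_grn([])
        rp = ranking([(("A", "B"), 1.0)])
        assert len(restrict_to_gold(rp, gold)) == 0


class TestPRCurve:
    def test_perfect_ranking_has_unit_aupr(self):
        gold = make_grn([("A", "B"), ("B", "C")])
        rp = ranking([(("A", "B"), 3.0), (("B", "C"), 2.0), (("C", "A"), 1.0)])
        assert pr_curve(rp, gold).auc == pytest.approx(1.0)

    def test_fp_first_matches_enumeration_oracle(self):
        gold = make_grn([("A", "B"), ("B", "C")])
        rp = ranking([(("C", "A"), 3.0), (("A", "B"), 2.0), (("B", "C"), 1.0)])
        assert pr_curve(rp, gold).auc == pytest.approx(
            brute_force_aupr([0, 1, 1], n_pos=2)
        )

    def test_all_tied_collapses_to_single_point(self):
        gold = make_grn([("A", "B"), ("B", "C")])
        rp = RankedPredictions(
            [("A", "B", 1.0), ("B", "C", 1.0), ("C", "A", 1.0)]
        )
        result = pr_curve(rp, gold)
        assert len(result.points) == 1
        assert result.auc == pytest.approx(result.points[0][1])

    def test_zero_positive_gold_errors(self):
        with pytest.raises(GRNError):
            pr_curve(ranking([(("A", "B"), 1.0)]), make_grn([]))

    def test_monotone_score_transform_invariance(self):
        gold = make_grn([("A", "B"), ("C", "D")])
        base = [(("A", "B"), 5.0), (("B", "A"), 3.0), (("C", "D"), 2.0)]
        rp1 = ranking(base)
        rp2 = ranking([(p, math.exp(s)) for p, s in base])
        assert pr_curve(rp1, gold).auc == pytest.approx(pr_curve(rp2, gold).auc)


class TestROCCurve:
    def test_perfect_ranking(self):
        gold = make_grn([("A", "B"), ("B", "C")])
        universe = gold_universe_size(gold)  # 2 regulators x 3 genes
        rp = ranking([(("A", "B"), 2.0), (("B", "C"), 1.0)])
        assert roc_curve(rp, gold, universe).auc == pytest.approx(1.0)

    def test_all_tied_is_random_equivalent(self):
        gold = make_grn([("A", "B"), ("B", "C")])
        pairs = [(r, t) for r in ("A", "B") for t in ("A", "B", "C")]
        rp = RankedPredictions([(r, t, 1.0) for r, t in pairs])
        assert roc_curve(rp, gold).auc == pytest.approx(0.5)

    def test_unranked_remainder_appended_as_tied_block(self):
        gold = make_grn([("A", "B"), ("B", "C")])
        rp = ranking([(("A", "B"), 1.0)])  # one TP ranked, rest unranked
        auc = roc_curve(rp, gold).auc
        # first point (0, 0.5), then straight line to (1,1)
        assert auc == pytest.approx(0.75)

    def test_matches_mann_whitney_oracle(self, rng):
        """Tie-aware AUROC equals the Mann-Whitney U statistic identity."""
        genes = ["A", "B", "C"]
        gold = make_grn([("A", "B"), ("B", "C"), ("A", "A")])
        universe_pairs = [(r, t) for r in ("A", "B") for t in genes]
        positives = {("a", "b"), ("b", "c"), ("a", "a")}
        for _trial in range(200):
            scores = rng.integers(0, 4, size=len(universe_pairs)).astype(float)
            rp = RankedPredictions.from_scores(
                [(r, t, s) for (r, t), s in zip(universe_pairs, scores)]
            )
            auc = roc_curve(rp, gold, len(universe_pairs)).auc
            pos_scores = [
                s for (r, t), s in zip(universe_pairs, scores)
                if (r.casefold(), t.casefold()) in positives
            ]
            neg_scores = [
                s for (r, t), s in zip(universe_pairs, scores)
                if (r.casefold(), t.casefold()) not in positives
            ]
            u = stats.mannwhitneyu(pos_scores, neg_scores, alternative="two-sided")
            expected = u.statistic / (len(pos_scores) * len(neg_scores))
            assert auc == pytest.approx(expected, abs=1e-12)

    def test_zero_negatives_errors(self):
        gold = make_grn([("A", "A")])
        with pytest.raises(GRNError):
            roc_curve(ranking([(("A", "A"), 1.0)]), gold, universe_size=1)


class TestSetScores:
    def test_perfect_prediction(self):
        universe = set("ABCDEFG")
        s = gr_prediction_scores({"A", "B"}, {"A", "B"}, universe)
        assert s.mcc == pytest.approx(1.0) and s.f1 == pytest.approx(1.0)

    def test_balanced_table_gives_zero_mcc(self):
        s = gr_prediction_scores({"A", "B"}, {"A", "C"}, {"A", "B", "C", "D"})
        assert s.counts.tp == s.counts.fp == s.counts.fn == s.counts.tn == 1
        assert s.mcc == pytest.approx(0.0)

    def test_disjoint_prediction_is_negative(self):
        s = gr_prediction_scores({"A"}, {"B"}, {"A", "B", "C"})
        assert s.mcc < 0

    def test_mcc_symmetric_in_predicted_and_gold(self):
        universe = set("ABCDEFGH")
        a = gr_prediction_scores({"A", "B", "C"}, {"B", "D"}, universe)
        b = gr_prediction_scores({"B", "D"}, {"A", "B", "C"}, universe)
        assert a.mcc == pytest.approx(b.mcc)

    def test_zero_marginal_defines_mcc_zero(self):
        s = gr_prediction_scores(set(), {"A"}, {"A", "B"})
        assert s.mcc == 0.0

    def test_empty_universe_errors(self):
        with pytest.raises(GRNError):
            gr_prediction_scores(set(), set(), set())


class TestSimpson:
    def test_identical_sets_score_one(self):
        s = {"a", "b", "c", "d", "e"}
        assert simpson_index(s, set(s)) == 1.0

    def test_subset_scores_one(self):
        assert simpson_index({"a"}, {"a", "b", "c"}) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert simpson_index({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert simpson_index({"a", "b"}, {"b", "c", "d"}) == pytest.approx(0.5)

    @given(
        a=st.frozensets(st.integers(0, 10), max_size=8),
        b=st.frozensets(st.integers(0, 10), max_size=8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, a, b):
        if not a and not b:
            with pytest.raises(GRNError):
                simpson_index(set(a), set(b))
            return
        s = simpson_index(set(a), set(b))
        assert s == simpson_index(set(b), set(a))
        assert 0.0 <= s <= 1.0
        if a and b and (a <= b or b <= a):
            assert s == 1.0

    def test_both_empty_errors(self):
        with pytest.raises(GRNError):
            simpson_index(set(), set())
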