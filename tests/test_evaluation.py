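"""Tie-aware ROC geometry, truncated AUC, E-value sweeps, congruence."""

import numpy as np
import pandas as pd
import pytest

from pmdabench.evaluation import (
    EvaluationError,
    auc_n,
    confusion_at_cutoffs,
    congruence_table,
    evaluate_scored_pairs,
    roc_curve,
)
from helpers import make_scored, shuffle_average_roc


def _auc_full(scored):
    result = evaluate_scored_pairs(scored, n_cutoff=10**9)
    return result.auc_n


class TestRocCurve:
    def test_single_tie_run_is_one_diagonal_segment(self):
        scored = make_scored([(5.0, "positive"), (5.0, "negative")])
        np.testing.assert_array_equal(roc_curve(scored), [[0, 0], [1, 1]])

    def test_strictly_ordered_scores_step_through_vertices(self):
        scored = make_scored(
            [(3.0, "positive"), (1.0, "positive"), (2.0, "negative"), (0.0, "negative")]
        )
        np.testing.assert_array_equal(
            roc_curve(scored), [[0, 0], [0, 1], [1, 1], [1, 2], [2, 2]]
        )

    def test_proxy_pairs_join_the_zero_score_tie_run(self):
        scored = make_scored(
            [(4.0, "positive"), (0.0, "positive!proxy"), (0.0, "negative!proxy")]
        )
        np.testing.assert_array_equal(roc_curve(scored), [[0, 0], [0, 1], [1, 2]])

    def test_single_class_input_is_an_error(self):
        with pytest.raises(EvaluationError, match="N=0"):
            roc_curve(make_scored([(1.0, "positive"), (2.0, "positive")]))

    def test_monotone_vertices(self, rng):
        scored = make_scored(
            [(float(rng.integers(0, 6)), "positive" if rng.random() < 0.5 else "negative")
             for _ in range(100)]
        )
        pts = roc_curve(scored)
        assert (np.diff(pts, axis=0) >= 0).all()
        assert tuple(pts[0]) == (0.0, 0.0)


class TestAucN:
    def test_perfect_separation_is_one(self):
        scored = make_scored([(9.0, "positive")] * 3 + [(1.0, "negative")] * 4)
        assert _auc_full(scored) == 1.0

    def test_all_tied_is_exactly_half(self):
        scored = make_scored([(2.0, "positive")] * 5 + [(2.0, "negative")] * 3)
        assert _auc_full(scored) == 0.5

    def test_worked_example_three_quarters(self):
        scored = make_scored(
            [(3.0, "positive"), (1.0, "positive"), (2.0, "negative"), (0.0, "negative")]
        )
        result = evaluate_scored_pairs(scored, n_cutoff=2)
        assert result.auc_n == 0.75
        # cutoff far beyond N truncates at N and gives the same value
        assert _auc_full(scored) == 0.75

    def test_truncation_uses_only_early_false_positives(self):
        # one negative outscores everything; the rest are clean
        scored = make_scored(
            [(10.0, "negative")] + [(5.0, "positive")] * 4 + [(1.0, "negative")] * 9
        )
        full = evaluate_scored_pairs(scored, n_cutoff=10).auc_n
        early = evaluate_scored_pairs(scored, n_cutoff=1).auc_n
        assert early == 0.0  # all positives come after the first FP
        assert full > 0.8

    def test_cutoff_mid_segment_interpolates(self):
        # one tie run of 2 positives + 2 negatives: diagonal; truncate at FP=1
        scored = make_scored([(2.0, "positive")] * 2 + [(2.0, "negative")] * 2)
        result = evaluate_scored_pairs(scored, n_cutoff=1)
        assert result.auc_n == 0.25  # triangle under half the diagonal

    def test_invalid_cutoff_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(EvaluationError):
            auc_n(pts, 0, 1, 1)


class TestShuffleOracle:
    def test_polyline_matches_mean_over_tie_orderings(self, rng):
        n = 200
        scores = rng.integers(0, 8, size=n).astype(float)  # many ties
        positive = rng.random(n) < 0.5
        if positive.all():
            positive[0] = False
        if not positive.any():
            positive[0] = True
        scored = make_scored(
            [(s, "positive" if p else "negative") for s, p in zip(scores, positive)]
        )
        mean_auc, se, mean_tp = shuffle_average_roc(scores, positive, 2000, rng)
        tie_auc = _auc_full(scored)
        assert abs(tie_auc - mean_auc) <= 3 * se + 1e-12
        # polyline vertices are exact: after a whole tie run the cumulative
        # (FP, TP) is the same under every ordering, so the curve must pass
        # through the step curve's run boundaries exactly
        pts = roc_curve(scored)
        order = np.argsort(-scores, kind="stable")
        lab = positive[order].astype(int)
        s_sorted = scores[order]
        fp = tp = 0
        expected_vertices = [(0.0, 0.0)]
        i = 0
        while i < len(s_sorted):
            j = i
            while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
                j += 1
            tp += int(lab[i:j].sum())
            fp += (j - i) - int(lab[i:j].sum())
            expected_vertices.append((float(fp), float(tp)))
            i = j
        np.testing.assert_array_equal(pts, expected_vertices)

    def test_score_shift_invariance(self, rng):
        values = [(float(rng.integers(0, 5)), "positive" if rng.random() < 0.4 else "negative")
                  for _ in range(60)]
        shifted = [(v + 100.0, r) for v, r in values]
        a = roc_curve(make_scored(values))
        b = roc_curve(make_scored(shifted))
        np.testing.assert_array_equal(a, b)
        assert _auc_full(make_scored(values)) == _auc_full(make_scored(shifted))

    def test_negating_scores_flips_auc(self, rng):
        values = [(float(rng.integers(0, 8)), "positive" if rng.random() < 0.5 else "negative")
                  for _ in range(80)]
        negated = [(-v, r) for v, r in values]
        assert _auc_full(make_scored(values)) == pytest.approx(
            1.0 - _auc_full(make_scored(negated))
        )


class TestConfusionAtCutoffs:
    def test_hand_enumerated_example(self):
        scored = make_scored(
            [(30.0, "positive"), (3.0, "positive"), (0.0, "positive!proxy"),
             (6.0, "negative")]
        )
        # e_value = 2^-bits: pos {1e-9ish, 0.125, proxy}, neg {0.015625}
        [c] = confusion_at_cutoffs(scored, [0.02])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 2, 1, 0)

    def test_infinite_cutoff_finds_everything_found(self):
        scored = make_scored([(5.0, "positive"), (2.0, "negative")])
        [c] = confusion_at_cutoffs(scored, [float("inf")])
        assert c.fn == 0 and c.tn == 0

    def test_impossible_cutoff_predicts_nothing(self):
        scored = make_scored([(5.0, "positive"), (2.0, "negative")])
        [c] = confusion_at_cutoffs(scored, [1e-300])
        assert c.tp == 0 and c.fp == 0

    def test_proxy_pairs_never_predicted_homologous(self):
        scored = make_scored([(0.0, "positive!proxy"), (5.0, "negative")])
        [c] = confusion_at_cutoffs(scored, [float("inf")])
        assert c.fn == 1  # the proxy positive stays unpredicted

    def test_recall_monotone_and_totals_fixed_as_cutoff_loosens(self, rng):
        scored = make_scored(
            [(float(rng.integers(0, 30)),
              "positive" if rng.random() < 0.5 else "negative")
             for _ in range(120)]
        )
        cutoffs = [1e-6, 1e-3, 0.1, 1.0, 100.0]
        results = confusion_at_cutoffs(scored, cutoffs)
        recalls = [c.recall for c in results]
        assert recalls == sorted(recalls)
        assert len({c.tp + c.fn for c in results}) == 1
        assert len({c.fp + c.tn for c in results}) == 1

    def test_empty_cutoff_list_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_cutoffs(make_scored([(1.0, "positive")]), [])


def _labels_frame(rows):
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "pfam", "superfamily", "gene3d"])


class TestCongruenceTable:
    def test_identical_labels_give_all_hundreds(self):
        rows = [
            (f"a{i}", f"b{i}", "homologous", "homologous", "homologous")
            for i in range(5)
        ] + [
            (f"c{i}", f"d{i}", "non_homologous", "non_homologous", "non_homologous")
            for i in range(5)
        ]
        table = congruence_table(_labels_frame(rows))
        assert (table["homologous_in_b_pct"] == 100.0).all()
        assert (table["ambiguous_in_b_pct"] == 0.0).all()
        assert (table["non_homologous_in_b_pct"] == 0.0).all()

    def test_rows_sum_to_hundred_percent(self):
        rows = [
            (f"a{i}", f"b{i}", "homologous",
             "ambiguous" if i % 3 == 0 else "homologous",
             "non_homologous" if i == 1 else "homologous")
            for i in range(10)
        ]
        table = congruence_table(_labels_frame(rows))
        sums = (
            table["homologous_in_b_pct"]
            + table["ambiguous_in_b_pct"]
            + table["non_homologous_in_b_pct"]
        )
        assert np.allclose(sums, 100.0, atol=0.02)

    def test_ninety_ten_split(self):
        rows = [
            (f"a{i}", f"b{i}", "homologous",
             "ambiguous" if i == 0 else "homologous", "homologous")
            for i in range(10)
        ]
        table = congruence_table(_labels_frame(rows))
        row = table[(table.scheme_a == "pfam") & (table.scheme_b == "superfamily")].iloc[0]
        assert row["homologous_in_b_pct"] == 90.0
        assert row["ambiguous_in_b_pct"] == 10.0
        assert row["non_homologous_in_b_pct"] == 0.0

    def test_uncovered_pairs_excluded_from_counts(self):
        rows = [
            ("a0", "b0", "homologous", "homologous", "homologous"),
            ("a1", "b1", "homologous", "uncovered", "homologous"),
        ]
        table = congruence_table(_labels_frame(rows))
        row = table[(table.scheme_a == "pfam") & (table.scheme_b == "superfamily")].iloc[0]
        assert row["homologous_in_a"] == 1  # the uncovered pair is dropped

    def test_no_fully_covered_pair_is_an_error(self):
        rows = [("a0", "b0", "homologous", "uncovered", "homologous")]
        with pytest.raises(EvaluationError, match="covered"):
            congruence_table(_labels_frame(rows))
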