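"""Evaluation suite: confusion counting, multiclass metrics, Wilson interval,
SUS scoring, engine comparison, and the load harness."""

import math
import random
import time

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutrikiosk.evaluation import (
    ConfusionCounts,
    confusion_from_predictions,
    compare_engines,
    load_test,
    metrics,
    round_half_up,
    summarize_sus,
    sus_grade,
    sus_score,
    wilson_interval,
)
from nutrikiosk.cohort import LABELS
from tests.test_cohort import record

CLASSES = ("A", "B", "C")


def counts(tp, fp, fn):
    support = {c: tp[c] + fn[c] for c in tp}
    return ConfusionCounts(classes=tuple(tp), tp=tp, fp=fp, fn=fn, support=support)


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion_from_predictions(["A"] * 5 + ["B"] * 5, ["A"] * 5 + ["B"] * 5, CLASSES)
        assert all(c.fp[k] == 0 and c.fn[k] == 0 for k in CLASSES)

    def test_single_mismatch(self):
        c = confusion_from_predictions(["A"], ["B"], CLASSES)
        assert c.fn["A"] == 1 and c.fp["B"] == 1 and c.tp["A"] == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion_from_predictions(["A"], ["A", "B"], CLASSES)

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_from_predictions(["Z"], ["A"], CLASSES)

    def test_against_brute_force_tally(self):
        rng = random.Random(7)
        truth = [rng.choice(CLASSES) for _ in range(300)]
        pred = [rng.choice(CLASSES) for _ in range(300)]
        c = confusion_from_predictions(truth, pred, CLASSES)
        for k in CLASSES:
            assert c.tp[k] == sum(1 for t, p in zip(truth, pred) if t == p == k)
            assert c.fn[k] == sum(1 for t, p in zip(truth, pred) if t == k != p)
            assert c.fp[k] == sum(1 for t, p in zip(truth, pred) if p == k != t)
        assert sum(c.fp.values()) == sum(c.fn.values())
        assert sum(c.tp.values()) + sum(c.fn.values()) == 300


class TestMetrics:
    def test_published_confusion_table_reproduced(self):
        """The three printed class rows yield exactly the printed metrics."""
        c = counts(
            tp={"Adequate": 152, "Minor": 74, "Consult": 36},
            fp={"Adequate": 16, "Minor": 13, "Consult": 9},
            fn={"Adequate": 13, "Minor": 16, "Consult": 9},
        )
        rep = metrics(c)
        assert rep.per_class["Adequate"] == {"precision": 90.5, "recall": 92.1, "f1": 91.3}
        assert rep.per_class["Minor"] == {"precision": 85.1, "recall": 82.2, "f1": 83.6}
        assert rep.per_class["Consult"] == {"precision": 80.0, "recall": 80.0, "f1": 80.0}

    def test_all_correct_gives_100(self):
        c = counts(
            tp={"A": 5, "B": 3, "C": 2},
            fp={"A": 0, "B": 0, "C": 0},
            fn={"A": 0, "B": 0, "C": 0},
        )
        rep = metrics(c)
        assert rep.micro_accuracy == 100.0
        assert all(v == 100.0 for d in rep.per_class.values() for v in d.values())

    def test_undefined_precision_warns_as_zero(self):
        c = counts(
            tp={"A": 5, "B": 0, "C": 2},
            fp={"A": 2, "B": 0, "C": 1},
            fn={"A": 1, "B": 2, "C": 0},
        )
        rep = metrics(c)
        assert rep.per_class["B"]["precision"] == 0.0
        assert "precision_undefined:B" in rep.warnings

    @given(st.lists(st.sampled_from(CLASSES), min_size=30, max_size=200))
    @settings(max_examples=100, derandomize=True)
    def test_weighted_recall_equals_micro_accuracy(self, truth):
        """Single-label identity: support-weighted recall == pooled accuracy."""
        rng = random.Random(0)
        if not all(c in truth for c in CLASSES):
            return
        pred = [rng.choice(CLASSES) for _ in truth]
        rep = metrics(confusion_from_predictions(truth, pred, CLASSES))
        assert rep.weighted["recall"] == rep.micro_accuracy

    def test_rounding_half_up(self):
        assert round_half_up(80.05, 1) == 80.1
        assert round_half_up(89.165, 2) == 89.17


class TestWilson:
    def test_published_success_rate_interval(self):
        lo, hi = wilson_interval(59, 60, 0.95)
        assert round_half_up(100 * lo, 1) == 91.1
        assert round_half_up(100 * hi, 1) == 99.7

    def test_zero_successes_lower_bound_zero(self):
        lo, _ = wilson_interval(0, 25, 0.95)
        assert lo == 0.0

    @pytest.mark.parametrize("k,n", [(1, 10), (5, 17), (59, 60), (30, 200)])
    def test_agrees_with_score_test_inversion(self, k, n):
        """Oracle: the interval is the set of p not rejected by the score
        test; recover it by two-stage grid inversion to 1e-6 resolution."""
        z = 1.959963984540054  # 97.5th normal percentile
        phat = k / n

        def accepted(p):
            se = math.sqrt(p * (1 - p) / n)
            return abs(phat - p) <= z * se + 1e-15

        coarse = np.linspace(0, 1, 100_001)
        inside = coarse[[accepted(p) for p in coarse]]
        lo_est, hi_est = inside[0], inside[-1]
        fine_lo = np.arange(max(lo_est - 2e-5, 0), lo_est + 2e-5, 1e-7)
        fine_hi = np.arange(hi_est - 2e-5, min(hi_est + 2e-5, 1.0), 1e-7)
        lo_oracle = next(p for p in fine_lo if accepted(p))
        hi_oracle = next(p for p in reversed(fine_hi) if accepted(p))
        lo, hi = wilson_interval(k, n, 0.95)
        assert lo == pytest.approx(lo_oracle, abs=1e-6)
        assert hi == pytest.approx(hi_oracle, abs=1e-6)

    @given(n=st.integers(1, 200), k1=st.integers(0, 200), k2=st.integers(0, 200))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_successes_and_contains_estimate(self, n, k1, k2):
        k1, k2 = min(k1, n), min(k2, n)
        if k1 > k2:
            k1, k2 = k2, k1
        lo1, hi1 = wilson_interval(k1, n)
        lo2, hi2 = wilson_interval(k2, n)
        assert lo1 <= lo2 + 1e-12 and hi1 <= hi2 + 1e-12
        assert lo1 - 1e-12 <= k1 / n <= hi1 + 1e-12

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            wilson_interval(5, 0)
        with pytest.raises(ValueError):
            wilson_interval(7, 5)


class TestSus:
    def test_maximal_score(self):
        assert sus_score([5, 1, 5, 1, 5, 1, 5, 1, 5, 1]) == 100.0

    def test_midpoint(self):
        assert sus_score([3] * 10) == 50.0

    def test_mixed_responses_hand_scored(self):
        # odd items (5,4,5,5,4) -> 18; even items (2,1,2,1,2) -> 17; 35*2.5
        assert sus_score([5, 2, 4, 1, 5, 2, 5, 1, 4, 2]) == 87.5

    def test_wrong_count_or_range(self):
        with pytest.raises(ValueError):
            sus_score([3] * 9)
        with pytest.raises(ValueError):
            sus_score([3] * 9 + [6])

    @given(st.lists(st.integers(1, 5), min_size=10, max_size=10))
    @settings(max_examples=100, derandomize=True)
    def test_parity_group_permutation_invariance(self, items):
        """Swapping responses among odd positions (or among even positions)
        cannot change the score."""
        odd = [items[i] for i in range(0, 10, 2)]
        even = [items[i] for i in range(1, 10, 2)]
        shuffled = []
        for o, e in zip(odd[::-1], even[::-1]):
            shuffled += [o, e]
        assert sus_score(items) == sus_score(shuffled)

    def test_published_evaluator_summary(self):
        out = summarize_sus([87.5, 92.5, 87.5])
        assert out["mean"] == 89.17 and out["sd"] == 2.89

    def test_identical_scores_zero_sd(self):
        assert summarize_sus([70.0, 70.0, 70.0])["sd"] == 0.0

    def test_two_scores(self):
        out = summarize_sus([80.0, 90.0])
        assert out["mean"] == 85.0 and out["sd"] == 7.07

    def test_grades(self):
        assert sus_grade(89.17) == "A+"
        assert sus_grade(82.0) == "A"
        assert sus_grade(40.0) == "F"

    def test_needs_two_scores(self):
        with pytest.raises(ValueError):
            summarize_sus([90.0])


class TestCompareEngines:
    def test_baseline_vs_itself_all_deltas_zero(self):
        rng = random.Random(3)
        recs = [record(label=rng.choice(LABELS)) for _ in range(60)]
        rule = lambda r: r.label  # noqa: E731
        res = compare_engines(recs, lambda rs: [rule(r) for r in rs], rule)
        assert res["delta"]["micro_accuracy"] == 0.0
        assert all(v == 0.0 for v in res["delta"]["macro"].values())

    def test_swap_flips_delta_sign(self):
        rng = random.Random(4)
        recs = [record(label=rng.choice(LABELS)) for _ in range(90)]
        fwd = compare_engines(recs, lambda rs: [r.label for r in rs], lambda r: "ADEQUATE")
        rev = compare_engines(recs, lambda rs: ["ADEQUATE"] * len(rs), lambda r: r.label)
        assert fwd["delta"]["micro_accuracy"] == -rev["delta"]["micro_accuracy"]


class TestLoadHarness:
    def test_latencies_recorded_per_request(self):
        results = load_test(lambda s: time.sleep(0.001), [1], requests_per_level=10, seed=0)
        (r,) = results
        assert len(r.latencies_s) == 10 and r.failures == 0
        manual_sd = float(np.std(r.latencies_s, ddof=1))
        assert r.sd_s == pytest.approx(manual_sd)

    def test_four_levels_give_four_rows(self):
        results = load_test(lambda s: None, [5, 10, 20, 50], requests_per_level=5, seed=0)
        assert [r.concurrency for r in results] == [5, 10, 20, 50]

    def test_all_failures_raise(self):
        def boom(seed):
            raise RuntimeError("down")

        with pytest.raises(RuntimeError, match="failed"):
            load_test(boom, [2], requests_per_level=4, seed=0)

    def test_partial_failures_counted(self):
        def flaky(seed):
            if seed % 2 == 0:
                raise RuntimeError("half down")

        (r,) = load_test(flaky, [2], requests_per_level=6, seed=0)
        assert r.failures == 3 and len(r.latencies_s) == 3
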