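"""Technical-evaluation suite: multiclass classification metrics from
confusion counts, the Wilson score interval for task-success proportions,
System Usability Scale (SUS) scoring with Sauro-Lewis curved grades, the
AI-versus-fixed-rules comparison, and a threaded concurrent-load harness.

Percentages are rounded half-up to one decimal — the convention needed for
exact ratios such as 74/87 to print as 85.1. Standard deviations are sample
(n-1) SDs throughout.
"""

from __future__ import annotations

import math
import os
import threading
import time
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .cohort import LABELS, CohortRecord

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "LoadTestResult",
    "confusion_from_predictions",
    "metrics",
    "wilson_interval",
    "sus_score",
    "summarize_sus",
    "sus_grade",
    "compare_engines",
    "load_test",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (0.05 at one decimal rounds to 0.1)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative counts with
    supports, for a closed three-class single-label problem."""

    classes: tuple[str, ...]
    tp: Mapping[str, int]
    fp: Mapping[str, int]
    fn: Mapping[str, int]
    support: Mapping[str, int]

    def __post_init__(self) -> None:
        for c in self.classes:
            if self.tp[c] + self.fn[c] != self.support[c]:
                raise ValueError(f"class {c}: tp + fn != support")
        if sum(self.fp.values()) != sum(self.fn.values()):
            raise ValueError("sum of false positives must equal sum of false negatives")

    @property
    def total(self) -> int:
        return sum(self.support.values())


@dataclass(frozen=True)
class MetricsReport:
    """All percentages, half-up rounded to 1 decimal."""

    per_class: dict[str, dict[str, float]]  # class -> {precision, recall, f1}
    macro: dict[str, float]
    weighted: dict[str, float]
    micro_accuracy: float
    warnings: tuple[str, ...] = ()


def confusion_from_predictions(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Sequence[str] = LABELS,
) -> ConfusionCounts:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    class_set = set(classes)
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    support = {c: 0 for c in classes}
    for t, p in zip(true_labels, predicted_labels):
        if t not in class_set or p not in class_set:
            raise ValueError(f"label outside class set: {t!r} / {p!r}")
        support[t] += 1
        if t == p:
            tp[t] += 1
        else:
            fn[t] += 1
            fp[p] += 1
    return ConfusionCounts(
        classes=tuple(classes), tp=tp, fp=fp, fn=fn, support=support
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Per-class precision/recall/F1 plus macro, support-weighted, and micro
    (overall accuracy) aggregates, as percentages at 1 decimal.

    A class with tp + fp = 0 has undefined precision; it is reported as 0
    with a warning flag so macro averages stay defined.
    """
    warnings: list[str] = []
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    f1: dict[str, float] = {}
    for c in counts.classes:
        if counts.support[c] <= 0:
            raise ValueError(f"class {c}: support must be > 0")
        denom = counts.tp[c] + counts.fp[c]
        if denom == 0:
            precision[c] = 0.0
            warnings.append(f"precision_undefined:{c}")
        else:
            precision[c] = counts.tp[c] / denom
        recall[c] = counts.tp[c] / counts.support[c]
        pr = precision[c] + recall[c]
        f1[c] = 2 * precision[c] * recall[c] / pr if pr > 0 else 0.0

    n = counts.total
    weights = {c: counts.support[c] / n for c in counts.classes}
    k = len(counts.classes)

    def pct(x: float) -> float:
        return round_half_up(100 * x, 1)

    per_class = {
        c: {"precision": pct(precision[c]), "recall": pct(recall[c]), "f1": pct(f1[c])}
        for c in counts.classes
    }
    macro = {
        "precision": pct(sum(precision.values()) / k),
        "recall": pct(sum(recall.values()) / k),
        "f1": pct(sum(f1.values()) / k),
    }
    weighted = {
        "precision": pct(sum(weights[c] * precision[c] for c in counts.classes)),
        "recall": pct(sum(weights[c] * recall[c] for c in counts.classes)),
        "f1": pct(sum(weights[c] * f1[c] for c in counts.classes)),
    }
    micro = pct(sum(counts.tp.values()) / n)
    return MetricsReport(
        per_class=per_class, macro=macro, weighted=weighted,
        micro_accuracy=micro, warnings=tuple(warnings),
    )


def wilson_interval(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, as proportions in
    [0, 1]."""
    if trials <= 0 or not 0 <= successes <= trials:
        raise ValueError("require 0 <= successes <= trials and trials > 0")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = norm.ppf(0.5 + confidence / 2)
    p = successes / trials
    denom = 1 + z**2 / trials
    center = (p + z**2 / (2 * trials)) / denom
    half = z * math.sqrt(p * (1 - p) / trials + z**2 / (4 * trials**2)) / denom
    # at the boundaries the exact bounds are 0 and 1; avoid float residue
    lower = 0.0 if successes == 0 else max(center - half, 0.0)
    upper = 1.0 if successes == trials else min(center + half, 1.0)
    return lower, upper


def sus_score(item_responses: Sequence[int]) -> float:
    """Standard SUS: ten 1-5 Likert items; odd items contribute response-1,
    even items 5-response; total times 2.5 gives a 0-100 score."""
    if len(item_responses) != 10:
        raise ValueError("SUS requires exactly 10 item responses")
    total = 0
    for i, r in enumerate(item_responses, start=1):
        if not (isinstance(r, (int, np.integer)) and 1 <= r <= 5):
            raise ValueError(f"item {i}: response {r!r} outside 1-5")
        total += (r - 1) if i % 2 == 1 else (5 - r)
    return total * 2.5


#: Sauro-Lewis curved grading scale (lower bound of each band, best first).
_SUS_GRADES = [
    (84.1, "A+"), (80.8, "A"), (78.9, "A-"), (77.2, "B+"), (74.1, "B"),
    (72.6, "B-"), (71.1, "C+"), (65.0, "C"), (62.7, "C-"), (51.7, "D"),
]


def sus_grade(score: float) -> str:
    for lo, grade in _SUS_GRADES:
        if score >= lo:
            return grade
    return "F"


def summarize_sus(scores: Sequence[float]) -> dict:
    """Mean, sample SD (both 2 decimals, half-up) and curved letter grade of
    per-evaluator SUS percentages."""
    if len(scores) < 2:
        raise ValueError("need at least 2 SUS scores")
    arr = np.asarray(scores, dtype=float)
    if arr.min() < 0 or arr.max() > 100:
        raise ValueError("SUS scores must be in [0, 100]")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return {
        "mean": round_half_up(mean, 2),
        "sd": round_half_up(sd, 2),
        "grade": sus_grade(mean),
        "n": len(scores),
    }


def compare_engines(
    test_records: Sequence[CohortRecord],
    model_predict: Callable[[Sequence[CohortRecord]], Sequence[str]],
    baseline_predict: Callable[[CohortRecord], str],
) -> dict:
    """Evaluate the MLP and the fixed-rule baseline on identical records.

    Returns both MetricsReports and a per-metric delta table (model minus
    baseline, in percentage points).
    """
    truth = [r.label for r in test_records]
    model_pred = list(model_predict(test_records))
    base_pred = [baseline_predict(r) for r in test_records]
    m_report = metrics(confusion_from_predictions(truth, model_pred))
    b_report = metrics(confusion_from_predictions(truth, base_pred))

    def delta(a: Mapping[str, float], b: Mapping[str, float]) -> dict[str, float]:
        return {k: round_half_up(a[k] - b[k], 1) for k in a}

    return {
        "model": m_report,
        "baseline": b_report,
        "delta": {
            "per_class": {
                c: delta(m_report.per_class[c], b_report.per_class[c])
                for c in m_report.per_class
            },
            "macro": delta(m_report.macro, b_report.macro),
            "weighted": delta(m_report.weighted, b_report.weighted),
            "micro_accuracy": round_half_up(
                m_report.micro_accuracy - b_report.micro_accuracy, 1
            ),
        },
    }


@dataclass
class LoadTestResult:
    concurrency: int
    latencies_s: list[float]
    mean_s: float
    sd_s: float
    failures: int
    cpu_percent: float | None = None
    ram_percent: float | None = None


def _ram_percent() -> float | None:
    try:
        with open("/proc/self/status") as fh:
            rss_kb = next(
                int(line.split()[1]) for line in fh if line.startswith("VmRSS:")
            )
        with open("/proc/meminfo") as fh:
            total_kb = next(
                int(line.split()[1]) for line in fh if line.startswith("MemTotal:")
            )
        return 100.0 * rss_kb / total_kb
    except (OSError, StopIteration):
        return None


def load_test(
    request_fn: Callable[[int], object],
    concurrency_levels: Sequence[int] = (5, 10, 20, 50),
    requests_per_level: int = 20,
    seed: int = 0,
) -> list[LoadTestResult]:
    """Concurrent-load harness over the in-process recommendation path.

    For each level, ``requests_per_level`` calls of ``request_fn`` (given a
    distinct integer request seed) are issued from that many threads;
    per-request wall-clock latencies are recorded and summarized with mean
    and sample SD. CPU and memory readings are best-effort and
    machine-dependent. Failures are counted and reported, never swallowed
    silently; a level with zero successes raises ``RuntimeError``.
    """
    results: list[LoadTestResult] = []
    for offset, level in enumerate(concurrency_levels):
        if level <= 0:
            raise ValueError("concurrency level must be positive")
        latencies: list[float] = []
        errors: list[Exception] = []
        lock = threading.Lock()
        cpu0 = os.times()
        wall0 = time.perf_counter()

        def worker(request_seed: int) -> None:
            t0 = time.perf_counter()
            try:
                request_fn(request_seed)
            except Exception as exc:  # noqa: BLE001 - reported in the result
                with lock:
                    errors.append(exc)
                return
            with lock:
                latencies.append(time.perf_counter() - t0)

        threads = []
        for i in range(requests_per_level):
            t = threading.Thread(
                target=worker, args=(seed + 100_000 * offset + i,), daemon=True
            )
            threads.append(t)
        # Launch in waves of `level` to emulate that many simultaneous users.
        for start in range(0, len(threads), level):
            wave = threads[start : start + level]
            for t in wave:
                t.start()
            for t in wave:
                t.join()

        if not latencies:
            raise RuntimeError(
                f"load level {level}: all {requests_per_level} requests failed "
                f"({errors[0] if errors else 'no error captured'})"
            )
        cpu1 = os.times()
        wall = time.perf_counter() - wall0
        cpu_pct = (
            100.0 * ((cpu1.user - cpu0.user) + (cpu1.system - cpu0.system)) / wall
            if wall > 0
            else None
        )
        arr = np.asarray(latencies)
        results.append(
            LoadTestResult(
                concurrency=level,
                latencies_s=latencies,
                mean_s=float(arr.mean()),
                sd_s=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                failures=len(errors),
                cpu_percent=cpu_pct,
                ram_percent=_ram_percent(),
            )
        )
    return results
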