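"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most literal possible
method (direct enumeration, re-summing, two-pass formulas) and share no
code with the implementation paths they check.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_transition_counts(order: int, history: list[int]) -> Counter:
    """Count every full (context, next) pair in the history, one by one."""
    pairs = Counter()
    for i in range(order, len(history)):
        pairs[(tuple(history[i - order : i]), history[i])] += 1
    return pairs


def brute_window_totals(score_rows: list[tuple[int, ...]], t: int, F: int) -> list[int]:
    """Re-sum per-member scores over rounds max(1, t-F) .. t-1 (1-based)."""
    if not score_rows:
        return []
    lo, hi = max(1, t - F), t - 1
    totals = [0] * len(score_rows[0])
    for round_no in range(lo, hi + 1):
        for i, s in enumerate(score_rows[round_no - 1]):
            totals[i] += s
    return totals


def brute_argmax_lowest(totals: list[int], orders: list[int]) -> int:
    """Max-scan for the dominant order, scanning every candidate."""
    best = max(totals)
    return min(o for o, s in zip(orders, totals) if s == best)


def brute_mean_std(xs: list[float]) -> tuple[float, float]:
    """Two-pass mean and sample (n-1) standard deviation."""
    n = len(xs)
    mean = sum(xs) / n
    if n < 2:
        return mean, 0.0
    return mean, math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))
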