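"""Independent brute-force oracles used only by the tests.

Each oracle deliberately avoids the implementation strategy of the code
it checks: plain recursion instead of dynamic programming, exhaustive
double loops instead of incremental bookkeeping, and an all-substrings
search (with an exact length-difference bound for pruning) instead of a
candidate length window.
"""

from __future__ import annotations

from typing import Optional, Sequence

import edlib

from sectionid.evaluation import span_overlap
from sectionid.resolver import ResolvedSection, Span


def levenshtein_recursive(a: str, b: str) -> int:
    """Exhaustive recursion on the textbook definition (tiny strings only)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[-1] == b[-1] else 1
    return min(
        levenshtein_recursive(a[:-1], b) + 1,
        levenshtein_recursive(a, b[:-1]) + 1,
        levenshtein_recursive(a[:-1], b[:-1]) + cost,
    )


def fuzzy_best_all_substrings(
    note: str, query: str, from_pos: int = 0
) -> Optional[tuple[Span, float]]:
    """Best-scoring substring over ALL lengths (no candidate window).

    Ties break toward the smaller start, then the shorter substring —
    the first candidate encountered in (start, length) iteration order.
    Candidates whose best-possible score (bounded by the length
    difference alone) cannot strictly beat the current best are skipped;
    the skip is exact, not an approximation.  Distances come from edlib,
    an implementation unrelated to the package's own.
    """
    n, q = len(note), len(query)
    best: Optional[tuple[Span, float]] = None
    best_score = float("-inf")
    for s in range(max(from_pos, 0), n):
        for length in range(1, n - s + 1):
            m = max(length, q)
            upper = 100.0 * (m - abs(length - q)) / m
            if upper <= best_score:
                if length >= q:  # upper bound only decreases from here on
                    break
                continue
            d = edlib.align(note[s : s + length], query, task="distance")["editDistance"]
            score = 100.0 * (m - d) / m
            if score > best_score:
                best = (Span(s, s + length - 1), score)
                best_score = score
    return best


def evaluate_directional_bruteforce(
    l1: Sequence[ResolvedSection], l2: Sequence[ResolvedSection]
) -> tuple[int, list[float], float, float]:
    """Double-loop re-implementation: explicit argmax per L1 section.

    Returns (n_correct, per-section ratios, accuracy, match ratio).
    """
    if not l1:
        return 0, [], 0.0, 0.0
    n_correct = 0
    ratios = []
    for s1 in l1:
        overlaps = [span_overlap(s1.span, s2.span) for s2 in l2]
        if overlaps:
            best_ov = max(overlaps)
            candidates = [i for i, ov in enumerate(overlaps) if ov == best_ov]
            winner = min(candidates, key=lambda i: (l2[i].span.start, i))
            ratios.append(best_ov / len(s1.span))
            if best_ov > 0 and l2[winner].label == s1.label:
                n_correct += 1
        else:
            ratios.append(0.0)
    return n_correct, ratios, n_correct / len(l1), sum(ratios) / len(ratios)
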