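"""Span-based evaluation of section identification.

Scoring is directional.  ``evaluate_directional(L1, L2)`` matches every
section in L1 against its best-overlapping counterpart in L2 and reports

* accuracy — the fraction of L1 sections whose best counterpart overlaps
  it and carries the same label, and
* match ratio — the mean, over L1 sections, of (overlap with the best
  counterpart) / (own length), a label-blind measure of span coverage.

Running the function in both directions gives precision and the
prediction match ratio (predictions against gold) and recall and the
target match ratio (gold against predictions); F1 is their harmonic mean
and the headline match ratio the mean of the two directional ratios.
Corpus-level scores are micro-aggregated — counts and per-section ratios
are pooled over notes before averaging — because section types are far
from evenly distributed.  Spans are 0-based inclusive throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from sectionid.resolver import ResolvedSection, Span


def span_overlap(a: Span, b: Span) -> int:
    """Number of character positions covered by both spans."""
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


@dataclasses.dataclass
class EvalOutcome:
    """Result of one directional evaluation."""

    n_correct: int
    ratios: list[float]
    accuracy: float
    match_ratio: float
    degenerate: bool = False  # True when L1 was empty

    @property
    def n_total(self) -> int:
        return len(self.ratios)


@dataclasses.dataclass
class PerTypeRow:
    label: str
    precision: float
    recall: float
    f1: float
    prediction_count: int
    prediction_match_ratio: float
    target_count: int
    target_match_ratio: float


@dataclasses.dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    prediction_match_ratio: float
    target_match_ratio: float
    match_ratio: float
    per_type: Optional[list[PerTypeRow]] = None

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        if self.per_type is None:
            d.pop("per_type")
        return d


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _best_counterpart(
    s1: ResolvedSection, l2: Sequence[ResolvedSection]
) -> tuple[Optional[ResolvedSection], int]:
    """Argmax-overlap counterpart; ties go to the earlier start, then list order."""
    best: Optional[ResolvedSection] = None
    best_ov = -1
    for s2 in l2:
        ov = span_overlap(s1.span, s2.span)
        if ov > best_ov or (ov == best_ov and best is not None and s2.span.start < best.span.start):
            best, best_ov = s2, ov
    return best, max(best_ov, 0)


def evaluate_directional(
    l1: Sequence[ResolvedSection], l2: Sequence[ResolvedSection]
) -> EvalOutcome:
    """Evaluate L1 against L2 (see module docstring).

    A section counts as correct only when its best counterpart both
    overlaps it (strictly positive overlap) and carries the same label.
    Empty L1 yields a degenerate all-zero outcome; empty L2 yields zero
    ratios for every L1 section.
    """
    if not l1:
        return EvalOutcome(0, [], 0.0, 0.0, degenerate=True)
    n_correct = 0
    ratios: list[float] = []
    for s1 in l1:
        s2, ov = _best_counterpart(s1, l2)
        ratios.append(ov / len(s1.span))
        if s2 is not None and ov > 0 and s2.label == s1.label:
            n_correct += 1
    return EvalOutcome(
        n_correct=n_correct,
        ratios=ratios,
        accuracy=n_correct / len(l1),
        match_ratio=sum(ratios) / len(ratios),
    )


def compute_metrics(
    pred: Sequence[ResolvedSection],
    gold: Sequence[ResolvedSection],
    per_type: bool = False,
) -> MetricsReport:
    """Precision/recall/F1 and match ratios for one note."""
    fwd = evaluate_directional(pred, gold)
    bwd = evaluate_directional(gold, pred)
    report = MetricsReport(
        precision=fwd.accuracy,
        recall=bwd.accuracy,
        f1=_f1(fwd.accuracy, bwd.accuracy),
        prediction_match_ratio=fwd.match_ratio,
        target_match_ratio=bwd.match_ratio,
        match_ratio=(fwd.match_ratio + bwd.match_ratio) / 2.0,
    )
    if per_type:
        report.per_type = per_type_report(pred, gold)
    return report


def micro_aggregate(
    per_note: Sequence[tuple[Sequence[ResolvedSection], Sequence[ResolvedSection]]],
    per_type: bool = False,
) -> MetricsReport:
    """Micro-aggregate (pred, gold) pairs over a corpus.

    Correct-match counts and section counts are summed across notes for
    precision and recall; per-section ratios are pooled across notes for
    the match ratios.
    """
    if not per_note:
        raise ValueError("micro_aggregate requires a non-empty corpus")
    fwd_correct = bwd_correct = 0
    fwd_ratios: list[float] = []
    bwd_ratios: list[float] = []
    for pred, gold in per_note:
        fwd = evaluate_directional(pred, gold)
        bwd = evaluate_directional(gold, pred)
        fwd_correct += fwd.n_correct
        bwd_correct += bwd.n_correct
        fwd_ratios.extend(fwd.ratios)
        bwd_ratios.extend(bwd.ratios)
    precision = fwd_correct / len(fwd_ratios) if fwd_ratios else 0.0
    recall = bwd_correct / len(bwd_ratios) if bwd_ratios else 0.0
    pmr = sum(fwd_ratios) / len(fwd_ratios) if fwd_ratios else 0.0
    tmr = sum(bwd_ratios) / len(bwd_ratios) if bwd_ratios else 0.0
    report = MetricsReport(
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        prediction_match_ratio=pmr,
        target_match_ratio=tmr,
        match_ratio=(pmr + tmr) / 2.0,
    )
    if per_type:
        report.per_type = per_type_micro(per_note)
    return report


def _directional_by_type(
    l1: Sequence[ResolvedSection], l2: Sequence[ResolvedSection]
) -> dict[str, tuple[int, list[float]]]:
    """Per-label (n_correct, ratios) tallies of L1 against the full L2."""
    out: dict[str, tuple[int, list[float]]] = {}
    for s1 in l1:
        s2, ov = _best_counterpart(s1, l2)
        correct = int(s2 is not None and ov > 0 and s2.label == s1.label)
        n, ratios = out.setdefault(s1.label, (0, []))
        ratios.append(ov / len(s1.span))
        out[s1.label] = (n + correct, ratios)
    return out


def _rows_from_tallies(
    fwd: dict[str, tuple[int, list[float]]],
    bwd: dict[str, tuple[int, list[float]]],
) -> list[PerTypeRow]:
    rows = []
    for label in sorted(set(fwd) | set(bwd)):
        fc, fr = fwd.get(label, (0, []))
        bc, br = bwd.get(label, (0, []))
        precision = fc / len(fr) if fr else 0.0
        recall = bc / len(br) if br else 0.0
        rows.append(
            PerTypeRow(
                label=label,
                precision=precision,
                recall=recall,
                f1=_f1(precision, recall),
                prediction_count=len(fr),
                prediction_match_ratio=sum(fr) / len(fr) if fr else 0.0,
                target_count=len(br),
                target_match_ratio=sum(br) / len(br) if br else 0.0,
            )
        )
    rows.sort(key=lambda r: (-r.f1, r.label))
    return rows


def per_type_report(
    pred: Sequence[ResolvedSection], gold: Sequence[ResolvedSection]
) -> list[PerTypeRow]:
    """Per-section-type metrics for one note, sorted by F1 descending.

    For each label, predictions of that label are scored against the full
    gold list (and vice versa), so a prediction matching a gold section of
    a different label counts as incorrect but still contributes its span
    coverage to the match ratio.
    """
    return _rows_from_tallies(
        _directional_by_type(pred, gold), _directional_by_type(gold, pred)
    )


def per_type_micro(
    per_note: Sequence[tuple[Sequence[ResolvedSection], Sequence[ResolvedSection]]],
) -> list[PerTypeRow]:
    """Per-type rows pooled over a corpus (micro, same pooling as above)."""
    fwd_all: dict[str, tuple[int, list[float]]] = {}
    bwd_all: dict[str, tuple[int, list[float]]] = {}
    for pred, gold in per_note:
        for pool, tallies in (
            (fwd_all, _directional_by_type(pred, gold)),
            (bwd_all, _directional_by_type(gold, pred)),
        ):
            for label, (n, ratios) in tallies.items():
                pn, pr = pool.setdefault(label, (0, []))
                pr.extend(ratios)
                pool[label] = (pn + n, pr)
    return _rows_from_tallies(fwd_all, bwd_all)
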