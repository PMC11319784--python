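"""Resolve model output into labeled character spans.

The model emits, per section, a name plus verbatim copies of the
section's opening and closing text.  Resolution maps these anchors back
to character offsets in the note:

1. drop sections whose name is not a schema name (exact match, or
   case-insensitive when enabled, resolving to the canonical casing);
2. drop sections whose start text cannot be located in the note (exact
   substring search, or fuzzy search when enabled);
3. locate each surviving start, walking the note with a moving cursor in
   emission order (search from the cursor, fall back to the whole note,
   advance the cursor past each located start);
4. sort by start offset, dropping later duplicates of an identical start;
5. tentatively end each section one character before the next section's
   start (the last section ends at the last character of the note);
6. search for the end text inside the tentative span; when found, the
   section ends at the final character of the rightmost qualifying
   match — otherwise the tentative end stands, so a section survives a
   badly copied end text as long as its start text is locatable.

Fuzzy matching scores candidate substrings by length-normalized
Levenshtein similarity, ``100 * (1 - d / max(|a|, |b|))`` on a 0-100
scale, and accepts matches scoring at or above a threshold (default 90).
Candidate lengths range over roughly +/-20% of the query length; at
similarity >= 90 the true best match cannot fall outside that window,
since similarity 90 already bounds the length difference by 10% of the
longer string.

Spans are 0-based with *inclusive* endpoints throughout the package.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from sectionid import _format
from sectionid.schema import SectionSchema


@dataclasses.dataclass(frozen=True)
class RawSection:
    """One parsed output block, before resolution."""

    index: int
    name_text: str
    start_text: str
    end_text: str

    def __post_init__(self) -> None:
        for field in ("name_text", "start_text", "end_text"):
            if not getattr(self, field).strip():
                raise ValueError(f"RawSection.{field} must be non-empty after trimming")


@dataclasses.dataclass(frozen=True, order=True)
class Span:
    """Character span, 0-based, inclusive on both ends."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid span [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass(frozen=True)
class ResolvedSection:
    label: str
    span: Span


@dataclasses.dataclass(frozen=True)
class ResolveOptions:
    """Matching variants for the resolution algorithm.

    ``case_insensitive_names`` relaxes step 1; ``fuzzy_spans`` switches
    steps 2 and 6 from exact substring search to fuzzy search at
    ``fuzzy_threshold`` (0-100 similarity scale).
    """

    case_insensitive_names: bool = False
    fuzzy_spans: bool = False
    fuzzy_threshold: float = 90.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fuzzy_threshold <= 100.0:
            raise ValueError("fuzzy_threshold must be in [0, 100]")


@dataclasses.dataclass
class ResolveStats:
    """Per-step bookkeeping of one note's resolution (debugging surface)."""

    n_raw: int = 0
    dropped_invalid_name: int = 0
    dropped_start_not_found: int = 0
    dropped_duplicate_start: int = 0
    dropped_empty_span: int = 0
    end_text_fallback: int = 0
    n_resolved: int = 0


def parse_output(raw: str) -> list[RawSection]:
    """Parse accepted model output into raw sections, in emission order.

    Text not matching the block format is skipped; fully unparseable
    input yields an empty list.
    """
    return [
        RawSection(b.index, b.name_text, b.start_text, b.end_text)
        for b in _format.iter_blocks(raw)
    ]


def levenshtein(a: str, b: str) -> int:
    """Edit distance with unit-cost insertions, deletions, substitutions."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def similarity(a: str, b: str) -> float:
    """Length-normalized Levenshtein similarity on a 0-100 scale.

    ``100 * (m - d) / m`` with ``m = max(|a|, |b|)``; two empty strings
    score 100 by convention.
    """
    m = max(len(a), len(b))
    if m == 0:
        return 100.0
    return 100.0 * (m - levenshtein(a, b)) / m


def find_exact(note: str, query: str, from_pos: int = 0) -> Optional[Span]:
    """Leftmost exact occurrence of ``query`` at or after ``from_pos``."""
    if not query:
        raise ValueError("query must be non-empty")
    i = note.find(query, max(from_pos, 0))
    if i < 0:
        return None
    return Span(i, i + len(query) - 1)


def _candidate_lengths(qlen: int) -> tuple[int, int]:
    lo = max(1, math.ceil(0.8 * qlen))
    hi = math.floor(1.2 * qlen) + 1
    return lo, hi


def _codes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("utf-32-le"), dtype=np.uint32)


def _scan_similarities(note: str, query: str, from_pos: int):
    """Similarity of every candidate substring in the length window.

    Returns ``(starts, lengths, sims)`` where ``sims[i, j]`` scores
    ``note[starts[i] : starts[i] + lengths[j]]`` against ``query``
    (``-inf`` where the candidate would overrun the note), or ``None``
    when no candidate fits.  One banded DP per start position is shared
    across all candidate lengths and vectorized over start positions.
    """
    n, q = len(note), len(query)
    lo, hi = _candidate_lengths(q)
    hi = min(hi, n - max(from_pos, 0))
    if hi < lo:
        return None
    starts = np.arange(max(from_pos, 0), n - lo + 1, dtype=np.int64)
    if starts.size == 0:
        return None
    codes = _codes(note)
    qcodes = _codes(query)
    S = starts.size
    big = np.int64(n + q + 1)
    prev = np.tile(np.arange(q + 1, dtype=np.int64), (S, 1))
    lengths = np.arange(lo, hi + 1, dtype=np.int64)
    dist = np.full((S, lengths.size), big, dtype=np.int64)
    cur = np.empty_like(prev)
    sentinel = np.uint32(0xFFFFFFFF)  # never equals a real code point
    for t in range(1, hi + 1):
        idx = starts + (t - 1)
        valid = idx < n
        ch = np.where(valid, codes[np.minimum(idx, n - 1)], sentinel)
        cur[:, 0] = t
        for j in range(1, q + 1):
            cost = (ch != qcodes[j - 1]).astype(np.int64)
            np.minimum(prev[:, j] + 1, cur[:, j - 1] + 1, out=cur[:, j])
            np.minimum(cur[:, j], prev[:, j - 1] + cost, out=cur[:, j])
        prev, cur = cur, prev
        if t >= lo:
            dist[:, t - lo] = np.where(valid, prev[:, q], big)
    m = np.maximum(lengths, q).astype(np.float64)
    sims = 100.0 * (m[None, :] - dist) / m[None, :]
    sims[dist >= big] = -np.inf
    return starts, lengths, sims


def find_fuzzy(
    note: str,
    query: str,
    from_pos: int = 0,
    threshold: float = 90.0,
) -> Optional[tuple[Span, float]]:
    """Best fuzzy match for ``query`` at or after ``from_pos``.

    Among candidate substrings with length within the +/-20% window,
    returns the one with maximum similarity if that maximum reaches
    ``threshold``; ties break toward the smaller start offset, then the
    shorter candidate.  An exact occurrence always wins (score 100).
    """
    if not query:
        raise ValueError("query must be non-empty")
    exact = find_exact(note, query, from_pos)
    if exact is not None:
        return exact, 100.0
    scan = _scan_similarities(note, query, from_pos)
    if scan is None:
        return None
    starts, lengths, sims = scan
    best = sims.max()
    if not best >= threshold:
        return None
    i, j = np.argwhere(sims == best)[0]  # row-major: min start, then min length
    s = int(starts[i])
    return Span(s, s + int(lengths[j]) - 1), float(best)


def _rightmost_exact(segment: str, query: str) -> Optional[Span]:
    i = segment.rfind(query)
    if i < 0:
        return None
    return Span(i, i + len(query) - 1)


def _rightmost_fuzzy(segment: str, query: str, threshold: float) -> Optional[Span]:
    """Rightmost qualifying fuzzy match within ``segment``.

    Position dominates score: among candidates scoring at or above the
    threshold, the one whose final character lies furthest right wins
    (ties toward the higher score, then the smaller start).
    """
    scan = _scan_similarities(segment, query, 0)
    if scan is None:
        return None
    starts, lengths, sims = scan
    qual = sims >= threshold
    if not qual.any():
        return None
    ends = starts[:, None] + lengths[None, :] - 1
    best_end = ends[qual].max()
    at_end = qual & (ends == best_end)
    best_score = sims[at_end].max()
    at_best = at_end & (sims == best_score)
    i, j = np.argwhere(at_best)[0]
    s = int(starts[i])
    return Span(s, s + int(lengths[j]) - 1)


def resolve_with_stats(
    note: str,
    raws: list[RawSection],
    schema: SectionSchema,
    opts: ResolveOptions = ResolveOptions(),
) -> tuple[list[ResolvedSection], ResolveStats]:
    """Run the resolution algorithm, returning per-step drop counts too."""
    stats = ResolveStats(n_raw=len(raws))
    names = set(schema.names)
    folded = {n.casefold(): n for n in schema.names}

    # step 1: valid section names
    named: list[tuple[str, RawSection]] = []
    for raw in raws:
        if raw.name_text in names:
            named.append((raw.name_text, raw))
        elif opts.case_insensitive_names and raw.name_text.casefold() in folded:
            named.append((folded[raw.name_text.casefold()], raw))
        else:
            stats.dropped_invalid_name += 1

    # steps 2-3: locate start texts with a moving cursor
    located: list[tuple[int, str, RawSection]] = []
    cursor = 0
    for label, raw in named:
        span = _find_start(note, raw.start_text, cursor, opts)
        if span is None and cursor > 0:
            span = _find_start(note, raw.start_text, 0, opts)
        if span is None:
            stats.dropped_start_not_found += 1
            continue
        located.append((span.start, label, raw))
        cursor = span.start + 1

    # step 4: sort by start offset, dedupe identical starts (keep first)
    located.sort(key=lambda item: item[0])
    deduped: list[tuple[int, str, RawSection]] = []
    for item in located:
        if deduped and item[0] == deduped[-1][0]:
            stats.dropped_duplicate_start += 1
            continue
        deduped.append(item)

    # steps 5-6: tentative ends, then end-text refinement
    out: list[ResolvedSection] = []
    for i, (start, label, raw) in enumerate(deduped):
        tentative = deduped[i + 1][0] - 1 if i + 1 < len(deduped) else len(note) - 1
        if tentative < start:
            stats.dropped_empty_span += 1
            continue
        window = note[start : tentative + 1]
        if opts.fuzzy_spans:
            hit = _rightmost_fuzzy(window, raw.end_text, opts.fuzzy_threshold)
        else:
            hit = _rightmost_exact(window, raw.end_text)
        if hit is None:
            stats.end_text_fallback += 1
            end = tentative
        else:
            end = start + hit.end
        out.append(ResolvedSection(label, Span(start, end)))
    stats.n_resolved = len(out)
    return out, stats


def _find_start(note: str, query: str, from_pos: int, opts: ResolveOptions) -> Optional[Span]:
    if opts.fuzzy_spans:
        hit = find_fuzzy(note, query, from_pos, opts.fuzzy_threshold)
        return hit[0] if hit is not None else None
    return find_exact(note, query, from_pos)


def resolve_sections(
    note: str,
    raws: list[RawSection],
    schema: SectionSchema,
    opts: ResolveOptions = ResolveOptions(),
) -> list[ResolvedSection]:
    """Resolve raw output blocks into labeled spans (see module docstring)."""
    sections, _ = resolve_with_stats(note, raws, schema, opts)
    return sections
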