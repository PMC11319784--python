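"""Synthetic sectioned notes and simulated model responses.

Real sectioned clinical corpora are access-restricted, so this module
fabricates what the rest of the pipeline needs: notes built as a heading
line plus a filler body per section, gold spans that exactly tile the
note, and model responses in the required output format whose failure
modes are injected with controllable probabilities — invalid section
names, case-mangled names, typos in the copied start/end anchors,
dropped sections, shuffled block order, and malformed blocks.  Bodies
are seeded pseudo-clinical word salad: the statistical structure that
matters downstream (headings, bodies, tiling spans, verbatim anchors) is
present, the language itself is not meant to be realistic.

With all error probabilities at zero the simulated response resolves
back to the gold spans exactly under all-exact matching, which anchors
the end-to-end round-trip tests.
"""

from __future__ import annotations

import collections
import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np

from sectionid.resolver import ResolvedSection, Span
from sectionid.schema import SectionSchema

_WORDS = (
    "patient stable afebrile alert oriented denies reports mild moderate "
    "severe chronic acute bilateral tenderness edema noted improved "
    "unchanged continued tolerated regular diet ambulating pain nausea "
    "vomiting fever chills cough dyspnea baseline monitor follow labs "
    "pending reviewed discussed plan care daily twice oral dose mg ml "
    "normal elevated decreased within limits exam unremarkable soft "
    "clear lungs heart rate rhythm abdomen extremities neuro intact"
).split()

# Default snippet length for copied start/end anchors: 30 characters keeps
# one or two injected edits comfortably above a 90-similarity threshold.
DEFAULT_SNIPPET_CHARS = 30


@dataclasses.dataclass(frozen=True)
class NoteRecipe:
    """Shape of a generated note.

    ``n_sections`` and ``body_chars`` are inclusive (low, high) ranges;
    each section is a heading line drawn from its type's example headings
    plus a filler body whose length is drawn from ``body_chars``.
    """

    n_sections: tuple[int, int] = (6, 12)
    body_chars: tuple[int, int] = (150, 400)

    def __post_init__(self) -> None:
        for name in ("n_sections", "body_chars"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise ValueError(f"{name} must be a non-empty positive range")


@dataclasses.dataclass(frozen=True)
class ErrorConfig:
    """Injection probabilities for simulated response errors."""

    p_invalid_name: float = 0.0
    p_case_flip: float = 0.0
    p_typo_start: float = 0.0
    p_typo_end: float = 0.0
    typo_edits: int = 1
    p_drop_section: float = 0.0
    p_reorder: float = 0.0
    p_malformed_block: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("p_") and not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be in [0, 1]")
        if self.typo_edits < 1:
            raise ValueError("typo_edits must be >= 1")


@dataclasses.dataclass
class CorpusBundle:
    """An aligned synthetic corpus: notes, gold spans, simulated responses."""

    notes: list[dict]  # {"note_id", "text"}
    gold: dict[str, list[ResolvedSection]]
    responses: dict[str, list[str]]  # note_id -> attempt list (mock script)
    manifest: dict

    def write(self, out_dir) -> None:
        """Write notes/gold/responses JSONL plus a manifest JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "notes.jsonl", "w", encoding="utf-8") as fh:
            for rec in self.notes:
                fh.write(json.dumps(rec) + "\n")
        with open(out / "gold.jsonl", "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"offsets": "0-based, inclusive [start, end]"}) + "\n")
            for note_id, sections in self.gold.items():
                fh.write(json.dumps(_sections_record(note_id, sections)) + "\n")
        with open(out / "responses.jsonl", "w", encoding="utf-8") as fh:
            for note_id, attempts in self.responses.items():
                fh.write(json.dumps({"note_id": note_id, "responses": attempts}) + "\n")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2)


def _sections_record(note_id: str, sections: list[ResolvedSection]) -> dict:
    return {
        "note_id": note_id,
        "sections": [
            {"label": s.label, "start": s.span.start, "end": s.span.end} for s in sections
        ],
    }


def _body(rng: np.random.Generator, n_chars: int) -> str:
    """Seeded filler prose of roughly ``n_chars`` characters."""
    out: list[str] = []
    length = 0
    while length < n_chars:
        n_words = int(rng.integers(5, 13))
        words = [str(rng.choice(_WORDS)) for _ in range(n_words)]
        sentence = words[0].capitalize() + " " + " ".join(words[1:]) + "."
        out.append(sentence)
        length += len(sentence) + 1
    return " ".join(out)


def generate_note(
    schema: SectionSchema,
    recipe: NoteRecipe,
    rng: np.random.Generator,
) -> tuple[str, list[ResolvedSection]]:
    """Generate one sectioned note and its gold spans.

    Section types are sampled without replacement from the schema's types
    that have example headings; each section is a heading line (original
    casing, colon-terminated) plus a filler body.  Gold spans are sorted,
    non-overlapping, and tile the note exactly.
    """
    eligible = [t for t in schema.types if t.example_headings]
    lo, hi = recipe.n_sections
    if len(eligible) < lo:
        raise ValueError(
            f"schema has only {len(eligible)} types with example headings; "
            f"recipe needs at least {lo}"
        )
    n = int(rng.integers(lo, min(hi, len(eligible)) + 1))
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=n, replace=False)]
    pieces: list[str] = []
    gold: list[ResolvedSection] = []
    offset = 0
    for t in chosen:
        heading = t.example_headings[int(rng.integers(len(t.example_headings)))]
        body_len = int(rng.integers(recipe.body_chars[0], recipe.body_chars[1] + 1))
        # Sections begin and end on non-whitespace (heading char / final
        # period) so whitespace-trimmed copied anchors still pin the exact
        # gold boundaries; the spans tile the note with no separator.
        text = f"{heading}:\n{_body(rng, body_len)}"
        gold.append(ResolvedSection(t.name, Span(offset, offset + len(text) - 1)))
        pieces.append(text)
        offset += len(text)
    return "".join(pieces), gold


_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _apply_typos(text: str, n_edits: int, rng: np.random.Generator, note: str) -> str:
    """Apply random single-character edits, guaranteeing the result is
    actually corrupted: different from the input and without an exact
    occurrence anywhere in the note."""
    for _ in range(20):
        chars = list(text)
        for _ in range(n_edits):
            op = int(rng.integers(3))
            pos = int(rng.integers(len(chars)))
            if op == 0 and len(chars) > 1:  # delete
                del chars[pos]
            elif op == 1:  # insert
                chars.insert(pos, _ALPHABET[int(rng.integers(26))])
            else:  # substitute with a different character
                repl = _ALPHABET[int(rng.integers(26))]
                while repl == chars[pos]:
                    repl = _ALPHABET[int(rng.integers(26))]
                chars[pos] = repl
        corrupted = "".join(chars)
        if corrupted != text and corrupted.strip() and corrupted not in note:
            return corrupted
    return text  # corruption kept colliding; leave the anchor intact


def _flip_case(label: str) -> str:
    flipped = label.upper()
    if flipped == label:
        flipped = label.lower()
    return flipped


def simulate_response(
    note_text: str,
    gold: list[ResolvedSection],
    schema: SectionSchema,
    err: ErrorConfig,
    rng: np.random.Generator,
    snippet_chars: int = DEFAULT_SNIPPET_CHARS,
    tally: Optional[collections.Counter] = None,
) -> str:
    """Simulate one model response for a note, with error injection.

    Each gold section (unless dropped) becomes one output block whose
    start/end texts are the first/last ``snippet_chars`` characters of
    the section.  Pass a ``tally`` counter to collect how many of each
    corruption were actually applied.
    """
    if tally is None:
        tally = collections.Counter()
    blocks: list[str] = []
    for section in gold:
        if rng.random() < err.p_drop_section:
            tally["dropped_section"] += 1
            continue
        name = section.label
        if rng.random() < err.p_invalid_name:
            name = f"Miscellaneous category {int(rng.integers(1000))}"
            tally["invalid_name"] += 1
        elif rng.random() < err.p_case_flip:
            name = _flip_case(name)
            if name != section.label:
                tally["case_flip"] += 1
        start, end = section.span.start, section.span.end
        k = min(snippet_chars, end - start + 1)
        start_text = note_text[start : start + k]
        end_text = note_text[end - k + 1 : end + 1]
        if rng.random() < err.p_typo_start:
            corrupted = _apply_typos(start_text, err.typo_edits, rng, note_text)
            if corrupted != start_text:
                tally["typo_start"] += 1
            start_text = corrupted
        if rng.random() < err.p_typo_end:
            corrupted = _apply_typos(end_text, err.typo_edits, rng, note_text)
            if corrupted != end_text:
                tally["typo_end"] += 1
            end_text = corrupted
        blocks.append(
            f"Section {len(blocks) + 1}: {name}\n"
            f"Starts at: {start_text}\n"
            f"Ends at: {end_text}"
        )
    if blocks and rng.random() < err.p_reorder:
        order = rng.permutation(len(blocks))
        if not np.array_equal(order, np.arange(len(blocks))):
            tally["reordered_response"] += 1
        blocks = [blocks[i] for i in order]
    if blocks and rng.random() < err.p_malformed_block:
        i = int(rng.integers(len(blocks)))
        blocks[i] = blocks[i].replace("Starts at:", "Starting around:")
        tally["malformed_block"] += 1
    return "\n\n".join(blocks)


def generate_corpus(
    schema: SectionSchema,
    recipe: NoteRecipe,
    err: ErrorConfig,
    n_notes: int,
    seed: int,
    snippet_chars: int = DEFAULT_SNIPPET_CHARS,
) -> CorpusBundle:
    """Generate an aligned corpus of notes, gold spans, and responses.

    Deterministic in ``(seed, n_notes)``: each note draws from its own
    counter-derived random stream, so regenerating the corpus reproduces
    it byte for byte.
    """
    if n_notes < 1:
        raise ValueError("n_notes must be >= 1")
    notes: list[dict] = []
    gold: dict[str, list[ResolvedSection]] = {}
    responses: dict[str, list[str]] = {}
    tally: collections.Counter = collections.Counter()
    for i in range(n_notes):
        rng = np.random.default_rng([seed, i])
        note_id = f"note-{i:04d}"
        text, sections = generate_note(schema, recipe, rng)
        notes.append({"note_id": note_id, "text": text})
        gold[note_id] = sections
        responses[note_id] = [
            simulate_response(text, sections, schema, err, rng, snippet_chars, tally)
        ]
    manifest = {
        "seed": seed,
        "n_notes": n_notes,
        "schema": schema.name,
        "recipe": dataclasses.asdict(recipe),
        "errors": dataclasses.asdict(err),
        "snippet_chars": snippet_chars,
        "n_gold_sections": sum(len(v) for v in gold.values()),
        "injected": dict(sorted(tally.items())),
    }
    return CorpusBundle(notes=notes, gold=gold, responses=responses, manifest=manifest)
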