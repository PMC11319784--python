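"""JSONL readers/writers for notes, span files, and generation logs.

Span files carry an optional leading header record documenting the
offset convention (0-based, inclusive endpoints); readers skip it.
"""

from __future__ import annotations

import json
from pathlib import Path

from sectionid.resolver import ResolvedSection, Span

OFFSETS_HEADER = {"offsets": "0-based, inclusive [start, end]"}


def _iter_records(path):
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)


def read_notes(path) -> list[dict]:
    """Read ``{"note_id", "text"}`` records."""
    notes = []
    for rec in _iter_records(path):
        notes.append({"note_id": str(rec["note_id"]), "text": rec["text"]})
    return notes


def read_sections(path) -> dict[str, list[ResolvedSection]]:
    """Read labeled spans keyed by note id, skipping the offsets header."""
    out: dict[str, list[ResolvedSection]] = {}
    for rec in _iter_records(path):
        if "note_id" not in rec:
            continue  # header record
        out[str(rec["note_id"])] = [
            ResolvedSection(s["label"], Span(int(s["start"]), int(s["end"])))
            for s in rec["sections"]
        ]
    return out


def write_sections(path, sections_by_note: dict[str, list[ResolvedSection]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(OFFSETS_HEADER) + "\n")
        for note_id, sections in sections_by_note.items():
            fh.write(
                json.dumps(
                    {
                        "note_id": note_id,
                        "sections": [
                            {"label": s.label, "start": s.span.start, "end": s.span.end}
                            for s in sections
                        ],
                    }
                )
                + "\n"
            )


def write_jsonl(path, records) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")
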