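"""Prompt assembly for section identification.

The prompt has four components, rendered in a fixed order: a system
message establishing the clinician persona, a task description, one
definition line per section type (name, free-text definition, example
headings), and the clinical note itself followed by an output cue.  Two
exemplar output blocks sit between the definitions and the note so the
model sees the exact shape it must emit.  Models are asked to copy each
section's opening and closing text verbatim rather than emit character
offsets, which generative models are unreliable at producing directly.
"""

from __future__ import annotations

import dataclasses

from sectionid.backend import check_format
from sectionid.schema import SectionSchema

DEFAULT_SYSTEM_MESSAGE = (
    "You are a helpful assistant. You are an experienced clinician and you "
    "are familiar with writing and understanding clinical notes."
)

DEFAULT_TASK_DESCRIPTION = (
    "A clinical note contains multiple sections like family history, "
    "allergies and history of present illness. Given a clinical note as an "
    "input, please separate the notes into sections and output their "
    "section names. Also specify where the section starts and ends. Use "
    "section names from one of the following:"
)

# Synthetic exemplars in the exact required output shape (not drawn from
# any real note).
DEFAULT_FORMAT_EXAMPLES = (
    "Section 1: Allergies\nStarts at: ALLERGIES:\nEnds at: rash to penicillin.",
    "Section 2: Social history\nStarts at: SOCIAL HISTORY:\nEnds at: denies tobacco use.",
)


@dataclasses.dataclass(frozen=True)
class PromptConfig:
    system_message: str = DEFAULT_SYSTEM_MESSAGE
    task_description: str = DEFAULT_TASK_DESCRIPTION
    format_examples: tuple[str, ...] = DEFAULT_FORMAT_EXAMPLES
    output_cue: str = "Output:"

    def __post_init__(self) -> None:
        object.__setattr__(self, "format_examples", tuple(self.format_examples))
        bad = [ex for ex in self.format_examples if not check_format(ex)]
        if bad:
            raise ValueError(
                f"{len(bad)} format example(s) do not pass the output format check"
            )


def render_section_definitions(schema: SectionSchema) -> str:
    """Render one definition line per section type, in schema order.

    Each line reads ``<name>: <definition>, example section headings
    include '<h1>', '<h2>'.``; types without example headings omit the
    headings clause.
    """
    lines = []
    for t in schema.types:
        if t.example_headings:
            quoted = ", ".join(f"'{h}'" for h in t.example_headings)
            lines.append(f"{t.name}: {t.definition}, example section headings include {quoted}.")
        else:
            lines.append(f"{t.name}: {t.definition}.")
    return "\n".join(lines)


def build_prompt(
    schema: SectionSchema,
    note_text: str,
    cfg: PromptConfig | None = None,
) -> tuple[str, str]:
    """Assemble the (system, user) message pair for one note.

    The user message concatenates task description, section definitions,
    exemplar output blocks, the note text verbatim, and the output cue,
    each block separated by a blank line.  Output is byte-deterministic
    for fixed inputs.  Non-chat backends may join the pair themselves.
    """
    if not note_text:
        raise ValueError("note_text must be non-empty")
    cfg = cfg or PromptConfig()
    blocks = [cfg.task_description, render_section_definitions(schema)]
    blocks.extend(cfg.format_examples)
    blocks.append(note_text)
    blocks.append(cfg.output_cue)
    user = "\n\n".join(blocks)
    return cfg.system_message, user
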