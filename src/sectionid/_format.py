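"""Grammar of the model's required output format.

Each extracted section must be emitted as a block of the shape::

    Section <integer>: <name text>
    Starts at: <start text>
    Ends at: <end text>

Keywords are case-sensitive; the three text fields are free text that may
span lines and run until the next keyword (or the next ``Section <n>:``
header, for the end text).  This module owns the single regex both the
backend's minimum-format check and the resolver's parser are built on.
"""

from __future__ import annotations

import re
from typing import Iterator, NamedTuple

BLOCK_RE = re.compile(
    r"Section\s+(?P<index>\d+)\s*:"
    r"(?P<name>.+?)"
    r"Starts at:"
    r"(?P<start>.+?)"
    r"Ends at:"
    r"(?P<end>.+?)"
    r"(?=Section\s+\d+\s*:|\Z)",
    re.DOTALL,
)


class Block(NamedTuple):
    index: int
    name_text: str
    start_text: str
    end_text: str


def iter_blocks(raw: str) -> Iterator[Block]:
    """Yield well-formed blocks in emission order, skipping other text.

    A block only counts if all three text fields are non-empty after
    trimming surrounding whitespace.
    """
    for m in BLOCK_RE.finditer(raw):
        name = m.group("name").strip()
        start = m.group("start").strip()
        end = m.group("end").strip()
        if name and start and end:
            yield Block(int(m.group("index")), name, start, end)
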