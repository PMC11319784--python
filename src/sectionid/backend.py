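"""Backends for querying a generative model, with format-checked retries.

Models occasionally emit output that does not follow the required section
format at all; rather than propagate garbage downstream, generation is
retried up to a budget and the first response containing at least one
well-formed section block is accepted.  A note whose attempts all fail
contributes zero predicted sections (it counts against recall) instead of
aborting a corpus run.

Two backends are provided: a deterministic :class:`MockBackend` replaying
scripted responses (for offline testing and simulation studies), and
:class:`HttpChatBackend`, which speaks the generic chat-completion HTTP
contract (``model``, ``messages``, ``temperature``) so any compatible
endpoint works.  Credentials come from the environment, never from config
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import urllib.error
import urllib.request
from typing import Optional, Sequence, Union

from sectionid import _format


class BackendError(RuntimeError):
    """Transport-level failure talking to a backend."""


def check_format(raw: str) -> bool:
    """Minimum format check: does ``raw`` contain at least one section block?

    A block is ``Section <int>: <text> Starts at: <text> Ends at: <text>``
    with case-sensitive keywords and non-empty text fields.
    """
    return next(_format.iter_blocks(raw), None) is not None


@dataclasses.dataclass
class BackendConfig:
    """Configuration for constructing a backend.

    ``kind`` is ``"mock"`` or ``"http_chat"``.  ``max_retries`` bounds the
    number of additional generations after the first (so at most
    ``1 + max_retries`` attempts per note).
    """

    kind: str = "mock"
    endpoint: str = ""
    model: str = ""
    api_key_env: str = "SECTIONID_API_KEY"
    temperature: float = 0.0
    max_retries: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("mock", "http_chat"):
            raise ValueError(f"unknown backend kind {self.kind!r}")
        if self.max_retries < 0:
            raise ValueError("max_retries must be >= 0")


@dataclasses.dataclass
class GenerationRecord:
    """Audit record of one note's generation attempts."""

    prompt_fingerprint: str
    attempts: list[str] = dataclasses.field(default_factory=list)
    accepted: Optional[str] = None
    n_retries_used: int = 0

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def fingerprint(system: str, user: str) -> str:
    h = hashlib.sha256()
    h.update(system.encode("utf-8"))
    h.update(b"\x00")
    h.update(user.encode("utf-8"))
    return h.hexdigest()[:16]


class MockBackend:
    """Deterministic backend replaying a script of canned responses.

    The script is either a flat sequence of responses (attempt ``i``
    returns element ``i``, clamped to the last) or a mapping from note id
    to such a sequence.  Identical (script, note id, attempt) always
    yields identical output, so whole corpus runs are reproducible.
    """

    kind = "mock"

    def __init__(
        self,
        script: Union[Sequence[str], dict[str, Sequence[str]]],
        seed: int = 0,
    ) -> None:
        self.script = script
        self.seed = seed

    def generate(self, system: str, user: str, *, note_id: Optional[str] = None,
                 attempt: int = 0) -> str:
        if isinstance(self.script, dict):
            if note_id is None or note_id not in self.script:
                raise BackendError(f"mock script has no responses for note {note_id!r}")
            responses = self.script[note_id]
        else:
            responses = self.script
        if not responses:
            raise BackendError("mock script is empty")
        return responses[min(attempt, len(responses) - 1)]

    @classmethod
    def from_jsonl(cls, path) -> "MockBackend":
        """Load a script from JSONL of ``{"note_id": ..., "responses": [...]}``."""
        script: dict[str, Sequence[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                script[str(rec["note_id"])] = list(rec["responses"])
        return cls(script)


class HttpChatBackend:
    """Generic chat-completion HTTP backend (stdlib transport).

    Sends ``{"model": ..., "messages": [system, user], "temperature": ...}``
    to the configured endpoint and reads the first choice's message
    content.  The bearer token is read from the environment variable named
    by ``cfg.api_key_env``.
    """

    kind = "http_chat"

    def __init__(self, cfg: BackendConfig, timeout: float = 120.0) -> None:
        if not cfg.endpoint:
            raise ValueError("http_chat backend requires an endpoint")
        self.cfg = cfg
        self.timeout = timeout

    def generate(self, system: str, user: str, *, note_id: Optional[str] = None,
                 attempt: int = 0) -> str:
        payload = {
            "model": self.cfg.model,
            "messages": [
                {"role": "system", "content": system},
                {"role": "user", "content": user},
            ],
            "temperature": self.cfg.temperature,
        }
        headers = {"Content-Type": "application/json"}
        key = os.environ.get(self.cfg.api_key_env, "")
        if key:
            headers["Authorization"] = f"Bearer {key}"
        req = urllib.request.Request(
            self.cfg.endpoint,
            data=json.dumps(payload).encode("utf-8"),
            headers=headers,
            method="POST",
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, ValueError) as exc:
            raise BackendError(f"chat endpoint request failed: {exc}") from exc
        try:
            return body["choices"][0]["message"]["content"]
        except (KeyError, IndexError, TypeError) as exc:
            raise BackendError(f"unexpected chat response shape: {body!r:.200}") from exc


def make_backend(cfg: BackendConfig, mock_script=None):
    """Construct a backend from its config (mock scripts passed separately)."""
    if cfg.kind == "mock":
        if mock_script is None:
            raise ValueError("mock backend requires a script")
        return MockBackend(mock_script, seed=cfg.seed)
    return HttpChatBackend(cfg)


def query_with_retry(
    backend,
    prompt: tuple[str, str],
    max_retries: int = 3,
    note_id: Optional[str] = None,
) -> GenerationRecord:
    """Generate with up to ``max_retries`` extra attempts on malformed output.

    The first response passing :func:`check_format` is accepted.  When all
    ``1 + max_retries`` attempts fail the check, the record carries no
    accepted response — the caller treats the note as yielding zero
    sections.  Transport failures raise :class:`BackendError` (annotated
    with the attempt count); format failures never raise.
    """
    system, user = prompt
    rec = GenerationRecord(prompt_fingerprint=fingerprint(system, user))
    for attempt in range(1 + max_retries):
        try:
            raw = backend.generate(system, user, note_id=note_id, attempt=attempt)
        except BackendError as exc:
            raise BackendError(f"attempt {attempt + 1}: {exc}") from exc
        rec.attempts.append(raw)
        if check_format(raw):
            rec.accepted = raw
            rec.n_retries_used = attempt
            return rec
    rec.n_retries_used = max_retries
    return rec
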