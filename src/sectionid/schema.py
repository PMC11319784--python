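"""Section-type schemas: canonical labels, free-text definitions, label maps.

A schema is the single source of truth for which section types exist, how
they are described to the model, and how raw annotation labels collapse
onto the canonical label set (many-to-one, with ``Unknown`` as the usual
catch-all for categories that would only confuse the model).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml

UNKNOWN_LABEL = "Unknown"

_BUNDLED = ("discharge", "progress")


class SchemaError(ValueError):
    """Raised when a schema config fails to parse or validate."""


class MappingError(KeyError):
    """Raised when a raw label cannot be mapped and no catch-all type exists."""


@dataclasses.dataclass(frozen=True)
class SectionType:
    """One canonical section type.

    Parameters
    ----------
    name
        Canonical label, unique within a schema (e.g. ``"Admit date"``).
    definition
        Free-text description shown to the model.
    example_headings
        Headings observed for this type in real notes, original casing.
    """

    name: str
    definition: str
    example_headings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise SchemaError("section type name must be non-empty")
        if not self.definition or not self.definition.strip():
            raise SchemaError(f"section type {self.name!r}: definition must be non-empty")
        object.__setattr__(self, "example_headings", tuple(self.example_headings))


@dataclasses.dataclass(frozen=True)
class SectionSchema:
    """Ordered collection of section types plus a raw-label map.

    Invariants enforced at construction: names are unique even ignoring
    case (case-insensitive matching must stay unambiguous), every
    ``label_map`` target is a canonical name, and at most one type is the
    ``Unknown`` catch-all.
    """

    types: tuple[SectionType, ...]
    label_map: dict[str, str] = dataclasses.field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "types", tuple(self.types))
        names = [t.name for t in self.types]
        folded: dict[str, str] = {}
        dupes = []
        for n in names:
            key = n.casefold()
            if key in folded:
                dupes.append((folded[key], n))
            folded[key] = n
        if dupes:
            listing = "; ".join(f"{a!r} vs {b!r}" for a, b in dupes)
            raise SchemaError(f"duplicate section names (ignoring case): {listing}")
        if sum(n == UNKNOWN_LABEL for n in names) > 1:
            raise SchemaError(f"more than one {UNKNOWN_LABEL!r} type")
        name_set = set(names)
        bad = {raw: tgt for raw, tgt in self.label_map.items() if tgt not in name_set}
        if bad:
            raise SchemaError(f"label_map targets not in schema: {sorted(bad.items())}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.types)

    @property
    def has_unknown(self) -> bool:
        return UNKNOWN_LABEL in set(self.names)

    def type_named(self, name: str) -> SectionType:
        for t in self.types:
            if t.name == name:
                return t
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.types)


def map_label(schema: SectionSchema, raw_label: str) -> str:
    """Collapse a raw annotation label onto its canonical section name.

    Resolution order: explicit ``label_map`` entry, then identity if the
    label is already canonical, then the ``Unknown`` catch-all if the
    schema defines one.  Anything else raises :class:`MappingError`.
    """
    if raw_label in schema.label_map:
        return schema.label_map[raw_label]
    if raw_label in set(schema.names):
        return raw_label
    if schema.has_unknown:
        return UNKNOWN_LABEL
    raise MappingError(
        f"label {raw_label!r} is not canonical, not mapped, and the schema "
        f"has no {UNKNOWN_LABEL!r} type"
    )


def _parse_schema_doc(doc: object, source: str) -> SectionSchema:
    if not isinstance(doc, dict):
        raise SchemaError(f"{source}: schema config must be a mapping at top level")
    if "types" not in doc:
        raise SchemaError(f"{source}: missing required key 'types'")
    raw_types = doc["types"]
    if not isinstance(raw_types, list):
        raise SchemaError(f"{source}: key 'types' must be a list")
    types = []
    for i, entry in enumerate(raw_types):
        if not isinstance(entry, dict) or "name" not in entry or "definition" not in entry:
            raise SchemaError(
                f"{source}: types[{i}] must be a mapping with keys 'name' and 'definition'"
            )
        headings = entry.get("example_headings", []) or []
        if not isinstance(headings, list) or not all(isinstance(h, str) for h in headings):
            raise SchemaError(f"{source}: types[{i}].example_headings must be a list of strings")
        try:
            types.append(
                SectionType(
                    name=str(entry["name"]),
                    definition=str(entry["definition"]),
                    example_headings=tuple(headings),
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{source}: types[{i}]: {exc}") from exc
    label_map = doc.get("label_map", {}) or {}
    if not isinstance(label_map, dict):
        raise SchemaError(f"{source}: key 'label_map' must be a mapping")
    try:
        return SectionSchema(
            types=tuple(types),
            label_map={str(k): str(v) for k, v in label_map.items()},
            name=str(doc.get("name", "")),
        )
    except SchemaError as exc:
        raise SchemaError(f"{source}: {exc}") from exc


def load_schema(path: Union[str, Path]) -> SectionSchema:
    """Load and validate a schema from a YAML config file."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise SchemaError(f"cannot read schema config {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: not valid YAML: {exc}") from exc
    return _parse_schema_doc(doc, str(path))


def write_schema(schema: SectionSchema, path: Union[str, Path]) -> None:
    """Serialize a schema back to the YAML config format (round-trips)."""
    doc = {
        "name": schema.name,
        "types": [
            {
                "name": t.name,
                "definition": t.definition,
                "example_headings": list(t.example_headings),
            }
            for t in schema.types
        ],
        "label_map": dict(schema.label_map),
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )


def bundled_schema(name: str) -> SectionSchema:
    """Load one of the schemas shipped with the package.

    ``discharge`` is a 27-type discharge-summary schema and ``progress``
    a 15-type progress-note schema.  Definitions and example headings are
    authored reconstructions intended as editable starting points, not
    clinically validated text; override with :func:`load_schema` on your
    own config for real use.
    """
    if name not in _BUNDLED:
        raise SchemaError(f"no bundled schema {name!r}; available: {_BUNDLED}")
    ref = resources.files("sectionid") / "schemas" / f"{name}.yaml"
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _parse_schema_doc(doc, f"bundled:{name}")


def available_bundled() -> Iterable[str]:
    return _BUNDLED
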