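"""Entry-level archetypes: parsing, validation and the packaged library.

An archetype constrains one entry (one clinical action, observation,
interpretation or intention) to an ordered list of elements, each holding a
single typed data value. Definitions are authored as one YAML document per
archetype; the packaged library ships the twelve concepts used throughout
the pipeline: diagnosis, episodes, limitation of life-sustaining treatment,
administered medication, cumulative drug dose, prescribed medication,
movements between units, clinical observations, laboratory observations,
patients, health problems, and procedures.

Element lists other than the diagnosis archetype are reconstructions from
the concepts' OMOP correspondences; the diagnosis entry is fixed to its six
documented elements (episode_id, diagnosis, diagnosis_datetime, patient_id,
diagnosis_id, source).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from ehrbridge.rm import ValueKind

ARCHETYPE_ID_PATTERN = re.compile(r"^[A-Za-z][A-Za-z0-9-]*\.[a-z][a-z0-9_]*\.v\d+$")


class ArchetypeError(ValueError):
    """Raised when an archetype definition cannot be parsed or validated."""


class ElementSpec(BaseModel):
    """One leaf node of the entry, holding a single data value."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    node_id: str = Field(min_length=1)
    name: str = Field(min_length=1)
    kind: ValueKind
    mandatory: bool = True
    terminology_binding: Optional[str] = None

    @model_validator(mode="after")
    def _binding_requires_coded(self) -> "ElementSpec":
        if self.terminology_binding is not None and self.kind is not ValueKind.CODED_TEXT:
            raise ValueError(
                f"element {self.node_id!r}: terminology_binding requires kind CODED_TEXT"
            )
        return self


class EntrySpec(BaseModel):
    """An entry: at least one element, node ids pairwise distinct, order kept."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str = Field(min_length=1)
    elements: List[ElementSpec] = Field(min_length=1)

    @model_validator(mode="after")
    def _unique_node_ids(self) -> "EntrySpec":
        seen: set[str] = set()
        for el in self.elements:
            if el.node_id in seen:
                raise ValueError(f"duplicate node_id {el.node_id!r} in entry {self.name!r}")
            seen.add(el.node_id)
        return self

    def element(self, node_id: str) -> ElementSpec:
        for el in self.elements:
            if el.node_id == node_id:
                return el
        raise KeyError(node_id)


class Archetype(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    archetype_id: str
    version: str = Field(min_length=1)
    language: str = Field(min_length=1)
    description: str = ""
    entry: EntrySpec

    @field_validator("archetype_id")
    @classmethod
    def _id_pattern(cls, v: str) -> str:
        if not ARCHETYPE_ID_PATTERN.match(v):
            raise ValueError(
                f"archetype_id {v!r} does not match pattern "
                "<origin>.<concept>.v<n> (e.g. EHRB-ENTRY.diagnosis.v1)"
            )
        return v

    @property
    def concept(self) -> str:
        """The concept token of the id, e.g. ``diagnosis``."""
        return self.archetype_id.split(".")[1]


def parse_archetype(definition_text: str) -> Archetype:
    """Parse one YAML archetype definition.

    Raises :class:`ArchetypeError` naming the offending line (YAML syntax)
    or field path (schema violation); unknown fields are rejected.
    """
    try:
        raw = yaml.safe_load(definition_text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ArchetypeError(f"archetype definition is not valid YAML{where}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ArchetypeError("archetype definition must be a YAML mapping")
    try:
        return Archetype.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ArchetypeError(f"invalid archetype definition: {paths}") from exc


def serialize_archetype(archetype: Archetype) -> str:
    """Emit the canonical YAML form (fixed key order, element order kept)."""
    doc = {
        "archetype_id": archetype.archetype_id,
        "version": archetype.version,
        "language": archetype.language,
        "description": archetype.description,
        "entry": {
            "name": archetype.entry.name,
            "elements": [
                {
                    "node_id": el.node_id,
                    "name": el.name,
                    "kind": el.kind.value,
                    "mandatory": el.mandatory,
                    **(
                        {"terminology_binding": el.terminology_binding}
                        if el.terminology_binding is not None
                        else {}
                    ),
                }
                for el in archetype.entry.elements
            ],
        },
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


@dataclass(frozen=True)
class Violation:
    archetype_id: str
    path: str
    message: str


@dataclass
class ValidationReport:
    violations: List[Violation] = field(default_factory=list)

    def add(self, archetype_id: str, path: str, message: str) -> None:
        self.violations.append(Violation(archetype_id, path, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


@dataclass
class ArchetypeLibrary:
    """An ordered collection of archetypes keyed by archetype_id."""

    members: List[Archetype]

    def get(self, archetype_id: str) -> Archetype:
        for a in self.members:
            if a.archetype_id == archetype_id:
                return a
        raise KeyError(archetype_id)

    def by_concept(self, concept: str) -> Archetype:
        for a in self.members:
            if a.concept == concept:
                return a
        raise KeyError(concept)

    def __contains__(self, archetype_id: str) -> bool:
        return any(a.archetype_id == archetype_id for a in self.members)

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> List[str]:
        return [a.archetype_id for a in self.members]


def validate_library(library: ArchetypeLibrary) -> ValidationReport:
    """Cross-archetype validation; violations are report content, not errors.

    Per-archetype structural rules are enforced at parse time, so this checks
    the library-level invariants: id uniqueness and coded terminology bindings.
    """
    report = ValidationReport()
    seen: set[str] = set()
    for a in library.members:
        if a.archetype_id in seen:
            report.add(a.archetype_id, "archetype_id", "duplicate archetype_id in library")
        seen.add(a.archetype_id)
        for el in a.entry.elements:
            if el.terminology_binding is not None and el.kind is not ValueKind.CODED_TEXT:
                report.add(
                    a.archetype_id,
                    f"entry.elements.{el.node_id}",
                    "terminology_binding on a non-coded element",
                )
    return report


def load_library(paths: Iterable[Path]) -> ArchetypeLibrary:
    members = []
    for p in sorted(paths):
        members.append(parse_archetype(Path(p).read_text(encoding="utf-8")))
    return ArchetypeLibrary(members=members)


def _data_dir() -> Path:
    return Path(str(resources.files("ehrbridge").joinpath("data")))


def builtin_library() -> ArchetypeLibrary:
    """The packaged twelve-archetype library."""
    d = _data_dir() / "archetypes"
    return load_library(d.glob("*.yaml"))
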