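"""Archetype-driven ETL from tabular source data to EHR extract XML.

A mapping spec binds every archetype element to a source table column plus
an optional transform (terminology binding, categorization, datetime
normalization). Each qualifying source row becomes one entry; entries are
packaged per (patient, archetype) into extract documents. Rows that cannot
populate a mandatory element are quarantined with a reason — never dropped —
so that source rows = emitted entries + quarantined rows holds exactly.

Extract XML is a documented, namespaced subset of the EN/ISO 13606 extract
structure (see ``data/extract.xsd``); serialization is deterministic and
``parse(serialize(x)) == x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, List, Literal, Mapping, Optional, Tuple
from zoneinfo import ZoneInfo

import pandas as pd
import yaml
from lxml import etree
from pydantic import BaseModel, ConfigDict, Field

from ehrbridge.archetypes import Archetype, ArchetypeLibrary, ValidationReport, builtin_library
from ehrbridge.rm import DataValue, ValueKind
from ehrbridge.terminology import CategoryRules, MappingTable

EXTRACT_NS = "urn:ehrbridge:extract:1"
_E = "{%s}" % EXTRACT_NS

_VALUE_TAGS = {
    ValueKind.CODED_TEXT: "coded-text",
    ValueKind.SIMPLE_TEXT: "simple-text",
    ValueKind.DATE_TIME: "date-time",
    ValueKind.QUANTITY: "quantity",
    ValueKind.IDENTIFIER: "identifier",
    ValueKind.BOOLEAN: "boolean",
}
_TAG_KINDS = {v: k for k, v in _VALUE_TAGS.items()}


class MappingError(ValueError):
    """The mapping spec is inconsistent with the archetype or source schema."""


class ExtractError(ValueError):
    """An extract document is invalid."""


class ElementBinding(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    column: str = Field(min_length=1)
    transform: Literal["identity", "bind_code", "categorize", "datetime_parse"] = "identity"
    local_system: Optional[str] = None  # bind_code
    dimension: Optional[str] = None  # categorize
    units_column: Optional[str] = None  # QUANTITY elements


class MappingSpec(BaseModel):
    """Per-element source bindings of one archetype onto one source table."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    archetype_id: str
    source_table: str = Field(min_length=1)
    elements: Dict[str, ElementBinding] = Field(min_length=1)

    @classmethod
    def from_yaml(cls, text: str) -> "MappingSpec":
        return cls.model_validate(yaml.safe_load(text))

    def validate_against(self, archetype: Archetype, source_columns: List[str]) -> None:
        """Raise :class:`MappingError` before any row is processed."""
        if self.archetype_id != archetype.archetype_id:
            raise MappingError(
                f"mapping targets {self.archetype_id!r}, got archetype "
                f"{archetype.archetype_id!r}"
            )
        node_ids = {el.node_id for el in archetype.entry.elements}
        unknown = set(self.elements) - node_ids
        if unknown:
            raise MappingError(f"mapping binds unknown elements: {sorted(unknown)}")
        missing = [
            el.node_id
            for el in archetype.entry.elements
            if el.mandatory and el.node_id not in self.elements
        ]
        if missing:
            raise MappingError(f"mandatory elements without a binding: {missing}")
        cols = set(source_columns)
        for node_id, b in self.elements.items():
            if b.column not in cols:
                raise MappingError(
                    f"element {node_id!r} bound to missing column {b.column!r}"
                )
            if b.units_column is not None and b.units_column not in cols:
                raise MappingError(
                    f"element {node_id!r} units bound to missing column {b.units_column!r}"
                )
            if b.transform == "bind_code" and not b.local_system:
                raise MappingError(f"element {node_id!r}: bind_code requires local_system")
            if b.transform == "categorize" and not b.dimension:
                raise MappingError(f"element {node_id!r}: categorize requires dimension")


class Provenance(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    source: str
    extracted_at: str


class Entry(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    archetype_id: str
    values: Dict[str, DataValue]


class EHRExtract(BaseModel):
    """One patient's normalized entries for one archetype batch."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    extract_id: str
    patient_id: str
    provenance: Provenance
    entries: List[Entry]


class ExtractConfig(BaseModel):
    """Build-time configuration (timezone and fixed provenance for idempotence)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    timezone: str = "Europe/Madrid"
    source_name: str = "HIS"
    extraction_timestamp: str = "2022-02-15T00:00:00+01:00"


@dataclass
class BuildReport:
    """Per-archetype build accounting; quarantined rows keep their reason."""

    archetype_id: str = ""
    rows_seen: int = 0
    entries_built: int = 0
    quarantined: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def conserved(self) -> bool:
        return self.rows_seen == self.entries_built + len(self.quarantined)

    def quarantine_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.quarantined, columns=["row_index", "reason"])


def _is_missing(raw: object) -> bool:
    if raw is None:
        return True
    if isinstance(raw, float) and math.isnan(raw):
        return True
    return isinstance(raw, str) and raw == ""


def _parse_datetime(raw: object, tz: ZoneInfo) -> str:
    ts = pd.Timestamp(str(raw))
    if ts.tzinfo is None:
        # DST fold/gap policy: ambiguous wall times take the DST side,
        # nonexistent ones shift forward — deterministic either way
        ts = ts.tz_localize(tz, ambiguous=True, nonexistent="shift_forward")
    return ts.isoformat()


def _build_value(
    raw: object,
    row: pd.Series,
    kind: ValueKind,
    binding: ElementBinding,
    terminology: Optional[MappingTable],
    categories: Optional[CategoryRules],
    config: ExtractConfig,
) -> DataValue:
    text = str(raw)
    if binding.transform == "bind_code":
        if terminology is None:
            raise MappingError("bind_code transform requires a mapping table")
        return terminology.bind(text, binding.local_system)
    if binding.transform == "categorize":
        if categories is None:
            raise MappingError("categorize transform requires category rules")
        category = categories.categorize(text, binding.dimension)
        if kind is ValueKind.CODED_TEXT:
            return DataValue.coded_text(category, "local")
        return DataValue.simple_text(category)
    if binding.transform == "datetime_parse" or kind is ValueKind.DATE_TIME:
        return DataValue.date_time(_parse_datetime(raw, ZoneInfo(config.timezone)))
    if kind is ValueKind.QUANTITY:
        if binding.units_column is None:
            raise MappingError("QUANTITY element binding requires units_column")
        units = row[binding.units_column]
        if _is_missing(units):
            raise ValueError("missing units")
        try:
            magnitude = Decimal(text)
        except InvalidOperation as exc:
            raise ValueError(f"non-numeric magnitude {text!r}") from exc
        return DataValue.quantity(magnitude, str(units))
    if kind is ValueKind.IDENTIFIER:
        return DataValue.identifier(text, scope=config.source_name)
    if kind is ValueKind.BOOLEAN:
        lowered = text.strip().lower()
        if lowered in {"1", "true", "t", "yes"}:
            return DataValue.boolean(True)
        if lowered in {"0", "false", "f", "no"}:
            return DataValue.boolean(False)
        raise ValueError(f"not a boolean: {text!r}")
    if kind is ValueKind.CODED_TEXT:
        # identity on an already-coded column: preserve as local coding
        return DataValue.coded_text(text, "local")
    return DataValue.simple_text(text)


def build_extracts(
    source: Mapping[str, pd.DataFrame],
    mapping: MappingSpec,
    archetype: Archetype,
    terminology: Optional[MappingTable] = None,
    categories: Optional[CategoryRules] = None,
    config: Optional[ExtractConfig] = None,
) -> Tuple[List[EHRExtract], BuildReport]:
    """Build one entry per qualifying source row, grouped per patient.

    Every CODED_TEXT element bound with ``bind_code`` passes through
    terminology binding. Rows failing mandatory-element population are
    quarantined to the report with a reason. Config errors (missing table or
    column) are raised before any row is processed.
    """
    config = config or ExtractConfig()
    if mapping.source_table not in source:
        raise MappingError(f"source has no table {mapping.source_table!r}")
    frame = source[mapping.source_table]
    mapping.validate_against(archetype, list(frame.columns))

    report = BuildReport(archetype_id=archetype.archetype_id)
    per_patient: Dict[str, List[Entry]] = {}
    for idx, row in frame.iterrows():
        report.rows_seen += 1
        values: Dict[str, DataValue] = {}
        failure: Optional[str] = None
        for el in archetype.entry.elements:
            binding = mapping.elements.get(el.node_id)
            if binding is None:
                continue  # optional element without a binding
            raw = row[binding.column]
            if _is_missing(raw):
                if el.mandatory:
                    failure = f"{el.node_id}: mandatory element missing"
                    break
                continue
            try:
                values[el.node_id] = _build_value(
                    raw, row, el.kind, binding, terminology, categories, config
                )
            except (ValueError, InvalidOperation) as exc:
                failure = f"{el.node_id}: {exc}"
                break
        if failure is not None:
            report.quarantined.append((int(idx), failure))
            continue
        patient = values["patient_id"].id_value
        per_patient.setdefault(patient, []).append(
            Entry(archetype_id=archetype.archetype_id, values=values)
        )
        report.entries_built += 1

    provenance = Provenance(
        source=config.source_name, extracted_at=config.extraction_timestamp
    )
    extracts = [
        EHRExtract(
            extract_id=f"{archetype.concept}-{patient}",
            patient_id=patient,
            provenance=provenance,
            entries=entries,
        )
        for patient, entries in sorted(per_patient.items())
    ]
    return extracts, report


# ---------------------------------------------------------------------------
# XML serialization


@lru_cache(maxsize=1)
def _xsd() -> etree.XMLSchema:
    path = Path(str(resources.files("ehrbridge").joinpath("data/extract.xsd")))
    return etree.XMLSchema(etree.parse(str(path)))


def check_entry(entry: Entry, archetype: Archetype) -> List[Tuple[str, str]]:
    """Conformance of one entry to its archetype: (path, message) violations."""
    violations: List[Tuple[str, str]] = []
    node_ids = {el.node_id for el in archetype.entry.elements}
    for node_id in entry.values:
        if node_id not in node_ids:
            violations.append((f"entry.{node_id}", "element not defined by archetype"))
    for el in archetype.entry.elements:
        value = entry.values.get(el.node_id)
        if value is None:
            if el.mandatory:
                violations.append(
                    (f"entry.{el.node_id}", "mandatory element not populated")
                )
            continue
        if value.kind is not el.kind:
            violations.append(
                (
                    f"entry.{el.node_id}",
                    f"data value kind {value.kind.value} != declared {el.kind.value}",
                )
            )
    return violations


def validate_extract_model(
    extract: EHRExtract, library: ArchetypeLibrary
) -> ValidationReport:
    report = ValidationReport()
    for i, entry in enumerate(extract.entries):
        if entry.archetype_id not in library:
            report.add(entry.archetype_id, f"entries.{i}", "unknown archetype_id")
            continue
        archetype = library.get(entry.archetype_id)
        for path, message in check_entry(entry, archetype):
            report.add(entry.archetype_id, f"entries.{i}.{path}", message)
    return report


def _value_element(value: DataValue) -> etree._Element:
    tag = _VALUE_TAGS[value.kind]
    node = etree.Element(_E + tag)
    if value.kind is ValueKind.CODED_TEXT:
        node.set("code", value.code)
        node.set("code-system", value.code_system)
        if value.display is not None:
            node.set("display", value.display)
    elif value.kind is ValueKind.SIMPLE_TEXT:
        node.text = value.text
    elif value.kind is ValueKind.DATE_TIME:
        node.set("value", value.timestamp)
    elif value.kind is ValueKind.QUANTITY:
        node.set("magnitude", str(value.magnitude))
        node.set("units", value.units)
    elif value.kind is ValueKind.IDENTIFIER:
        node.set("value", value.id_value)
        if value.scope is not None:
            node.set("scope", value.scope)
    elif value.kind is ValueKind.BOOLEAN:
        node.set("value", "true" if value.flag else "false")
    return node


def serialize_extract(
    extract: EHRExtract, library: Optional[ArchetypeLibrary] = None
) -> bytes:
    """Serialize to the documented extract XML dialect.

    The extract is validated against the archetype library first; an invalid
    extract is refused with its violation list. Optional elements without a
    value are omitted entirely (no empty tags). Output is deterministic.
    """
    library = library if library is not None else builtin_library()
    report = validate_extract_model(extract, library)
    if not report.ok:
        details = "; ".join(f"{v.path}: {v.message}" for v in report.violations)
        raise ExtractError(f"extract does not validate: {details}")

    root = etree.Element(_E + "extract", nsmap={None: EXTRACT_NS})
    root.set("extract_id", extract.extract_id)
    root.set("patient_id", extract.patient_id)
    prov = etree.SubElement(root, _E + "provenance")
    prov.set("source", extract.provenance.source)
    prov.set("extracted-at", extract.provenance.extracted_at)
    for entry in extract.entries:
        archetype = library.get(entry.archetype_id)
        e = etree.SubElement(root, _E + "entry")
        e.set("archetype_id", entry.archetype_id)
        for el in archetype.entry.elements:  # archetype order, stable
            value = entry.values.get(el.node_id)
            if value is None:
                continue
            holder = etree.SubElement(e, _E + "element")
            holder.set("node_id", el.node_id)
            holder.append(_value_element(value))
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _parse_value(node: etree._Element) -> DataValue:
    tag = etree.QName(node).localname
    kind = _TAG_KINDS[tag]
    if kind is ValueKind.CODED_TEXT:
        return DataValue.coded_text(
            node.get("code"), node.get("code-system"), node.get("display")
        )
    if kind is ValueKind.SIMPLE_TEXT:
        return DataValue.simple_text(node.text or "")
    if kind is ValueKind.DATE_TIME:
        return DataValue.date_time(node.get("value"))
    if kind is ValueKind.QUANTITY:
        return DataValue.quantity(Decimal(node.get("magnitude")), node.get("units"))
    if kind is ValueKind.IDENTIFIER:
        return DataValue.identifier(node.get("value"), node.get("scope"))
    return DataValue.boolean(node.get("value") == "true")


def parse_extract(xml: bytes | str | Path) -> EHRExtract:
    """Parse extract XML (validated against the shipped XSD) into the model."""
    if isinstance(xml, Path):
        doc = etree.parse(str(xml))
    else:
        if isinstance(xml, str):
            xml = xml.encode("utf-8")
        doc = etree.fromstring(xml).getroottree()
    schema = _xsd()
    if not schema.validate(doc):
        raise ExtractError(f"extract XML does not match schema: {schema.error_log}")
    root = doc.getroot()
    entries = []
    for e in root.findall(_E + "entry"):
        values = {}
        for holder in e.findall(_E + "element"):
            values[holder.get("node_id")] = _parse_value(holder[0])
        entries.append(Entry(archetype_id=e.get("archetype_id"), values=values))
    prov = root.find(_E + "provenance")
    return EHRExtract(
        extract_id=root.get("extract_id"),
        patient_id=root.get("patient_id"),
        provenance=Provenance(
            source=prov.get("source"), extracted_at=prov.get("extracted-at")
        ),
        entries=entries,
    )


def validate_extract(
    xml: bytes | str | Path, library: Optional[ArchetypeLibrary] = None
) -> ValidationReport:
    """Report (not raise) conformance of an extract document to the library."""
    library = library if library is not None else builtin_library()
    try:
        extract = parse_extract(xml)
    except ExtractError as exc:
        report = ValidationReport()
        report.add("", "extract", str(exc))
        return report
    return validate_extract_model(extract, library)
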