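"""Loading extract data into the ontology as typed instances.

Each validated entry becomes one instance of its concept class; each
populated element becomes one assertion, typed per the reference-model
data-value kind (structured node for coded text, quantity and identifier;
typed literal otherwise). Instance IRIs are deterministic hashes of
(archetype_id, patient_id, entry content), so reloading the same extract is
idempotent: no duplicate instances, no new triples. A batch either fully
loads or fully rolls back.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from rdflib import Graph, Literal, RDF, XSD

from ehrbridge.archetypes import Archetype, ArchetypeLibrary, builtin_library
from ehrbridge.extracts import EHRExtract, Entry, parse_extract, validate_extract_model
from ehrbridge.ontology import (
    INST,
    ISO,
    RM_LEAVES,
    STRUCTURED_KINDS,
    TripleGraph,
    concept_class,
    element_property,
)
from ehrbridge.rm import DataValue, ValueKind


class LoadError(ValueError):
    """The batch cannot be loaded; nothing was inserted."""


@dataclass
class InstanceBatch:
    """Accounting of one load: created IRIs and per-archetype entry counts."""

    extract_ids: List[str] = field(default_factory=list)
    instance_iris: List[str] = field(default_factory=list)
    counts: Dict[str, int] = field(default_factory=dict)
    triples_added: int = 0
    loaded_at: str = ""


def entry_iri(concept: str, patient_id: str, entry: Entry) -> str:
    """Deterministic instance IRI from the entry's archetype and content."""
    canonical = json.dumps(
        {
            "archetype_id": entry.archetype_id,
            "patient_id": patient_id,
            "values": {
                k: v.model_dump(mode="json") for k, v in sorted(entry.values.items())
            },
        },
        sort_keys=True,
    )
    digest = hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]
    return str(INST[f"{concept}/{digest}"])


def value_triples(
    inst: str, prop, value: DataValue, vnode_iri: str
) -> List[Tuple]:
    """The assertions one populated element contributes."""
    from rdflib import URIRef

    s = URIRef(inst)
    if value.kind in STRUCTURED_KINDS:
        v = URIRef(vnode_iri)
        triples = [(s, prop, v), (v, RDF.type, ISO[value.kind.value])]
        if value.kind is ValueKind.CODED_TEXT:
            triples.append((v, ISO.codeValue, Literal(value.code)))
            triples.append((v, ISO.codingScheme, Literal(value.code_system)))
            if value.display is not None:
                triples.append((v, ISO.displayName, Literal(value.display)))
        elif value.kind is ValueKind.QUANTITY:
            triples.append(
                (v, ISO.magnitude, Literal(value.magnitude, datatype=XSD.decimal))
            )
            triples.append((v, ISO.units, Literal(value.units)))
        else:  # IDENTIFIER
            triples.append((v, ISO.idValue, Literal(value.id_value)))
            if value.scope is not None:
                triples.append((v, ISO.scope, Literal(value.scope)))
        return triples
    if value.kind is ValueKind.DATE_TIME:
        lit = Literal(value.timestamp, datatype=XSD.dateTime)
    elif value.kind is ValueKind.BOOLEAN:
        lit = Literal(value.flag)
    else:
        lit = Literal(value.text)
    return [(s, prop, lit)]


def _entry_triples(archetype: Archetype, patient_id: str, entry: Entry) -> Tuple[str, List[Tuple]]:
    from rdflib import URIRef

    iri = entry_iri(archetype.concept, patient_id, entry)
    triples: List[Tuple] = [(URIRef(iri), RDF.type, concept_class(archetype))]
    for node_id, value in entry.values.items():
        prop = element_property(archetype, node_id)
        vnode = f"{iri}/{node_id}"
        triples.extend(value_triples(iri, prop, value, vnode))
    return iri, triples


def load_extract(
    xml: bytes | str | Path | EHRExtract,
    graph: TripleGraph,
    library: Optional[ArchetypeLibrary] = None,
) -> InstanceBatch:
    """Insert one extract's entries into the instances graph.

    The extract must validate against the archetype library, and every
    entry's archetype must have a concept ontology in the store; otherwise
    a :class:`LoadError` is raised and the store is left untouched.
    """
    return load_extracts([xml], graph, library)


def load_extracts(
    xmls: Iterable[bytes | str | Path | EHRExtract],
    graph: TripleGraph,
    library: Optional[ArchetypeLibrary] = None,
) -> InstanceBatch:
    """Batch form of :func:`load_extract` with all-or-nothing semantics."""
    library = library if library is not None else builtin_library()
    batch = InstanceBatch()
    staged = Graph()
    for xml in xmls:
        extract = xml if isinstance(xml, EHRExtract) else parse_extract(xml)
        report = validate_extract_model(extract, library)
        if not report.ok:
            v = report.violations[0]
            raise LoadError(
                f"extract {extract.extract_id!r} does not validate "
                f"({v.path}: {v.message}); batch rolled back"
            )
        for entry in extract.entries:
            archetype = library.get(entry.archetype_id)
            if len(graph.layer(1, archetype.concept)) == 0:
                raise LoadError(
                    f"no concept ontology for archetype {entry.archetype_id!r}; "
                    "batch rolled back"
                )
            iri, triples = _entry_triples(archetype, extract.patient_id, entry)
            for t in triples:
                staged.add(t)
            batch.instance_iris.append(iri)
            batch.counts[entry.archetype_id] = batch.counts.get(entry.archetype_id, 0) + 1
        batch.extract_ids.append(extract.extract_id)

    target = graph.instances
    before = len(target)
    for t in staged:
        target.add(t)
    batch.triples_added = len(target) - before
    batch.loaded_at = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return batch


def load_extract_dir(
    directory: Path | str,
    graph: TripleGraph,
    library: Optional[ArchetypeLibrary] = None,
) -> InstanceBatch:
    """Load every ``*.xml`` under a directory tree (sorted, recursive)."""
    paths = sorted(Path(directory).rglob("*.xml"))
    return load_extracts(paths, graph, library)
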