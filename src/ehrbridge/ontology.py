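"""Three-layer RDF representation of the archetyped concepts.

Layer 1 (concept): one small ontology per archetype — a class for the entry
and one property per element, standard-agnostic. Layer 2 (reference-model
mapping): each concept class is subclassed under ``iso13606:Entry`` and each
element property is annotated with its reference-model data-value class.
Layer 3 (OMOP mapping): classes are annotated with their OMOP CDM table and
element properties with the CDM column(s) they feed. Patient data lives in a
separate instances graph; schema and instances never mix.

Expressivity is deliberately limited to class/property declarations,
subclass axioms, domains/ranges and annotations — transformation is done by
mapping lookups and generated queries, not by a reasoner.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator
from rdflib import Dataset, Graph, Literal as RDFLiteral, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL

from ehrbridge.archetypes import Archetype, ArchetypeLibrary
from ehrbridge.omop_schema import OmopSchema, default_schema
from ehrbridge.rm import ValueKind

BASE = "http://ehrbridge.org/"
ISO = Namespace(BASE + "ns/iso13606#")
OMOP = Namespace(BASE + "ns/omop#")
MAP = Namespace(BASE + "ns/map#")
INST = Namespace(BASE + "id/")
GRAPH = Namespace(BASE + "graph/")

#: Data-value kinds represented as structured nodes (object properties).
STRUCTURED_KINDS = {ValueKind.CODED_TEXT, ValueKind.QUANTITY, ValueKind.IDENTIFIER}

#: Leaf properties of the structured reference-model data values.
RM_LEAVES = {
    ValueKind.CODED_TEXT: {"value": ISO.codeValue, "display": ISO.displayName},
    ValueKind.QUANTITY: {"value": ISO.magnitude, "units": ISO.units},
    ValueKind.IDENTIFIER: {"value": ISO.idValue},
}


class OntologyError(ValueError):
    pass


def arch_ns(concept: str) -> Namespace:
    return Namespace(f"{BASE}ns/arch/{concept}#")


def _bind(g: Graph) -> Graph:
    g.bind("iso13606", ISO)
    g.bind("omop", OMOP)
    g.bind("map", MAP)
    g.bind("owl", OWL)
    return g


def rm_ontology() -> Graph:
    """The packaged EN/ISO 13606 reference-model subset ontology."""
    g = _bind(Graph())
    g.add((ISO.Entry, RDF.type, OWL.Class))
    g.add((ISO.Element, RDF.type, OWL.Class))
    g.add((ISO.DataValue, RDF.type, OWL.Class))
    for kind in ValueKind:
        cls = ISO[kind.value]
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, ISO.DataValue))
    for kind, leaves in RM_LEAVES.items():
        for prop in leaves.values():
            g.add((prop, RDF.type, OWL.DatatypeProperty))
            g.add((prop, RDFS.domain, ISO[kind.value]))
    g.add((ISO.codingScheme, RDF.type, OWL.DatatypeProperty))
    g.add((ISO.codingScheme, RDFS.domain, ISO[ValueKind.CODED_TEXT.value]))
    g.add((ISO.scope, RDF.type, OWL.DatatypeProperty))
    g.add((ISO.scope, RDFS.domain, ISO[ValueKind.IDENTIFIER.value]))
    return g


def column_iri(table: str, column: str) -> URIRef:
    return OMOP[f"{table}.{column}"]


def omop_ontology(schema: Optional[OmopSchema] = None) -> Graph:
    """OMOP CDM ontology: one class per table, one property per column."""
    schema = schema or default_schema()
    g = _bind(Graph())
    for table, columns in schema.tables.items():
        tcls = OMOP[table]
        g.add((tcls, RDF.type, OWL.Class))
        g.add((tcls, RDFS.label, RDFLiteral(table)))
        for column, ctype in columns:
            prop = column_iri(table, column)
            g.add((prop, RDF.type, RDF.Property))
            g.add((prop, MAP.inTable, tcls))
            g.add((prop, RDFS.label, RDFLiteral(column)))
            g.add((prop, MAP.columnType, RDFLiteral(ctype)))
    return g


def concept_class(archetype: Archetype) -> URIRef:
    return arch_ns(archetype.concept)[archetype.entry.name]


def element_property(archetype: Archetype, node_id: str) -> URIRef:
    return arch_ns(archetype.concept)[node_id]


def build_concept_ontology(archetype: Archetype) -> Graph:
    """Layer 1: one class for the entry, one property per element."""
    g = _bind(Graph())
    ns = arch_ns(archetype.concept)
    g.bind(archetype.concept, ns)
    cls = concept_class(archetype)
    g.add((cls, RDF.type, OWL.Class))
    g.add((cls, RDFS.label, RDFLiteral(archetype.entry.name)))
    g.add((cls, MAP.archetypeId, RDFLiteral(archetype.archetype_id)))
    for el in archetype.entry.elements:
        prop = element_property(archetype, el.node_id)
        ptype = OWL.ObjectProperty if el.kind in STRUCTURED_KINDS else OWL.DatatypeProperty
        g.add((prop, RDF.type, ptype))
        g.add((prop, RDFS.domain, cls))
        g.add((prop, RDFS.label, RDFLiteral(el.name)))
        g.add((prop, MAP.valueKind, RDFLiteral(el.kind.value)))
    return g


def build_rm_mapping(concept_graph: Graph, rm: Optional[Graph] = None) -> Graph:
    """Layer 2: subclass each concept class under iso13606:Entry and type
    each element property with its reference-model data-value class."""
    rm = rm if rm is not None else rm_ontology()
    g = _bind(Graph())
    for t in rm:
        g.add(t)
    for cls in concept_graph.subjects(RDF.type, OWL.Class):
        g.add((cls, RDFS.subClassOf, ISO.Entry))
    for prop, kind_lit in concept_graph.subject_objects(MAP.valueKind):
        kind = ValueKind(str(kind_lit))
        g.add((prop, MAP.rmType, ISO[kind.value]))
        if kind in STRUCTURED_KINDS:
            g.add((prop, RDFS.range, ISO[kind.value]))
    return g


class ColumnTarget(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    column: str = Field(min_length=1)
    part: Literal["value", "units", "display"] = "value"


class OmopMappingRow(BaseModel):
    """One archetype's correspondence to an OMOP table and its columns.

    An element may feed several columns (a quantity feeds both the numeric
    column and a unit source-value column); a bare string is shorthand for
    a single value-part target.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    archetype_id: str
    omop_table: str
    elements: Dict[str, List[ColumnTarget]]

    @field_validator("elements", mode="before")
    @classmethod
    def _normalize(cls, v):
        if not isinstance(v, dict):
            return v
        out = {}
        for node_id, targets in v.items():
            if isinstance(targets, str):
                targets = [{"column": targets}]
            elif isinstance(targets, dict):
                targets = [targets]
            out[node_id] = targets
        return out


def load_omop_mapping(path: Optional[Path] = None) -> List[OmopMappingRow]:
    """The packaged archetype↔OMOP correspondence configuration."""
    if path is None:
        path = Path(
            str(resources.files("ehrbridge").joinpath("data/mappings/omop_mapping.yaml"))
        )
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return [OmopMappingRow.model_validate(row) for row in raw]


def build_omop_mapping(
    concept_graph: Graph,
    mapping_row: OmopMappingRow,
    omop: Optional[Graph] = None,
    archetype: Optional[Archetype] = None,
) -> Graph:
    """Layer 3: annotate the concept class with its OMOP table and each
    element property with the CDM column(s) it feeds.

    Every (table, column) pair named by the mapping must exist in the OMOP
    ontology; offenders are listed in the raised error.
    """
    omop = omop if omop is not None else omop_ontology()
    classes = list(concept_graph.subjects(RDF.type, OWL.Class))
    if not classes:
        raise OntologyError("concept graph contains no concept class")
    cls = classes[0]
    table_cls = OMOP[mapping_row.omop_table]
    if (table_cls, RDF.type, OWL.Class) not in omop:
        raise OntologyError(f"OMOP ontology has no table class {mapping_row.omop_table!r}")

    part_predicates = {
        "value": MAP.mapsToColumn,
        "units": MAP.unitsMapToColumn,
        "display": MAP.displayMapsToColumn,
    }
    offenders = []
    g = _bind(Graph())
    g.add((cls, MAP.mapsToTable, table_cls))
    declared = {
        str(s).rsplit("#", 1)[-1] for s in concept_graph.subjects(MAP.valueKind, None)
    }
    for node_id, targets in mapping_row.elements.items():
        if node_id not in declared:
            offenders.append(f"element {node_id!r} not in concept graph")
            continue
        prop = next(
            s for s in concept_graph.subjects(MAP.valueKind, None)
            if str(s).endswith(f"#{node_id}")
        )
        for target in targets:
            col = column_iri(mapping_row.omop_table, target.column)
            if (col, MAP.inTable, table_cls) not in omop:
                offenders.append(
                    f"column {mapping_row.omop_table}.{target.column} not in OMOP schema"
                )
                continue
            g.add((prop, part_predicates[target.part], col))
    if offenders:
        raise OntologyError("invalid OMOP mapping: " + "; ".join(offenders))
    return g


class TripleGraph:
    """Named-graph store for the layer ontologies and patient instances.

    Graphs: ``rm``, ``omop``, ``layer1/<concept>``, ``layer2/<concept>``,
    ``layer3/<concept>`` and ``instances``. Queries run over the union.
    """

    def __init__(self) -> None:
        self.ds = Dataset(default_union=True)
        _bind(self.ds)

    # -- graph accessors ----------------------------------------------------

    def graph(self, name: str) -> Graph:
        return self.ds.graph(GRAPH[name])

    @property
    def rm(self) -> Graph:
        return self.graph("rm")

    @property
    def omop(self) -> Graph:
        return self.graph("omop")

    @property
    def instances(self) -> Graph:
        return self.graph("instances")

    def layer(self, n: int, concept: str) -> Graph:
        return self.graph(f"layer{n}/{concept}")

    def concepts(self, layer: int = 1) -> List[str]:
        prefix = str(GRAPH[f"layer{layer}/"])
        return sorted(
            str(g.identifier)[len(prefix):]
            for g in self.ds.graphs()
            if str(g.identifier).startswith(prefix)
        )

    def layer_union(self, n: int) -> Graph:
        g = _bind(Graph())
        for concept in self.concepts(n):
            for t in self.layer(n, concept):
                g.add(t)
        return g

    # -- construction -------------------------------------------------------

    def add_graph(self, name: str, source: Graph) -> None:
        target = self.graph(name)
        for t in source:
            target.add(t)

    def build_layers(
        self,
        library: ArchetypeLibrary,
        mapping_rows: Iterable[OmopMappingRow],
        schema: Optional[OmopSchema] = None,
    ) -> None:
        """Build rm/omop graphs and all three layers for every archetype.

        Archetypes without an OMOP correspondence row get layers 1–2 only.
        """
        rm = rm_ontology()
        omop = omop_ontology(schema)
        self.add_graph("rm", rm)
        self.add_graph("omop", omop)
        rows = {r.archetype_id: r for r in mapping_rows}
        for archetype in library:
            concept = build_concept_ontology(archetype)
            self.add_graph(f"layer1/{archetype.concept}", concept)
            self.add_graph(f"layer2/{archetype.concept}", build_rm_mapping(concept, rm))
            row = rows.get(archetype.archetype_id)
            if row is not None:
                self.add_graph(
                    f"layer3/{archetype.concept}",
                    build_omop_mapping(concept, row, omop, archetype),
                )

    # -- persistence --------------------------------------------------------

    def save(self, path: Path | str) -> None:
        self.ds.serialize(destination=str(path), format="trig")

    @classmethod
    def load(cls, path: Path | str) -> "TripleGraph":
        tg = cls()
        tg.ds.parse(str(path), format="trig")
        return tg

    def save_turtle_layers(self, out_dir: Path | str) -> List[Path]:
        """Emit one Turtle file per layer per archetype plus rm/omop."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ["rm", "omop"]:
            p = out / f"{name}.ttl"
            self.graph(name).serialize(destination=str(p), format="turtle")
            written.append(p)
        for n in (1, 2, 3):
            for concept in self.concepts(n):
                p = out / f"layer{n}_{concept}.ttl"
                self.layer(n, concept).serialize(destination=str(p), format="turtle")
                written.append(p)
        return written

    # -- invariants ---------------------------------------------------------

    def check_layer_separation(self) -> List[str]:
        """Layer graphs hold no instances; the instance graph no schema."""
        problems = []
        inst_prefix = str(INST)
        for g in self.ds.graphs():
            gid = str(g.identifier)
            if not gid.startswith(str(GRAPH)):
                continue
            name = gid[len(str(GRAPH)):]
            if name == "instances":
                for s, p, o in g.triples((None, RDF.type, OWL.Class)):
                    problems.append(f"instances graph declares class {s}")
            else:
                for s in set(g.subjects()):
                    if str(s).startswith(inst_prefix):
                        problems.append(f"{name} graph contains instance data {s}")
        return problems
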