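"""Loading extracts as ontology instances: typing, counts, idempotence."""

import random

import pytest
from rdflib import RDF, XSD, Literal, URIRef

from ehrbridge.instances import LoadError, load_extract, load_extracts
from ehrbridge.ontology import (
    ISO,
    MAP,
    STRUCTURED_KINDS,
    TripleGraph,
    load_omop_mapping,
)
from ehrbridge.rm import ValueKind

from conftest import random_extract


@pytest.fixture()
def store(library):
    tg = TripleGraph()
    tg.build_layers(library, load_omop_mapping())
    return tg


def _expected_triples(extract, library):
    """Independent count: 1 typing triple per entry + per-element assertions."""
    total = 0
    for entry in extract.entries:
        total += 1
        for value in entry.values.values():
            if value.kind in STRUCTURED_KINDS:
                total += 2  # link + node typing
                if value.kind is ValueKind.CODED_TEXT:
                    total += 2 + (value.display is not None)
                elif value.kind is ValueKind.QUANTITY:
                    total += 2
                else:
                    total += 1 + (value.scope is not None)
            else:
                total += 1
    return total


def test_loading_a_diagnosis_extract_creates_one_typed_instance(
    library, store, terminology_table, category_rules
):
    import pandas as pd

    from ehrbridge.extracts import build_extracts
    from ehrbridge.pipeline import builtin_extract_mappings

    mapping = next(
        m for m in builtin_extract_mappings() if m.archetype_id.endswith("diagnosis.v1")
    )
    source = {
        "diagnoses": pd.DataFrame(
            [
                {
                    "diagnosis_id": "DXREC000001",
                    "episode_id": "EP000123",
                    "patient_id": "PAT00001",
                    "local_dx_code": "DX011",
                    "recorded_datetime": "2020-03-01 10:30:00",
                    "source": "HIS",
                }
            ]
        )
    }
    extracts, _ = build_extracts(
        source, mapping, library.by_concept("diagnosis"),
        terminology_table, category_rules,
    )
    batch = load_extract(extracts[0], store, library)
    assert batch.counts == {"EHRB-ENTRY.diagnosis.v1": 1}
    found = list(
        store.instances.query(
            "SELECT ?i WHERE { ?i ?p ?n . ?n iso13606:codeValue 'H40.9' . "
            "?n iso13606:codingScheme 'ICD-10-CM' . }",
            initNs={"iso13606": ISO},
        )
    )
    assert len(found) == 1


def test_empty_batch_changes_no_triples(store, library):
    before = len(store.instances)
    batch = load_extracts([], store, library)
    assert batch.triples_added == 0 and len(store.instances) == before


def test_triple_count_delta_matches_direct_oracle(store, library):
    rng = random.Random(99)
    extracts = [random_extract(rng, library) for _ in range(25)]
    expected = sum(_expected_triples(x, library) for x in extracts)
    batch = load_extracts(extracts, store, library)
    assert batch.triples_added == expected
    assert len(batch.instance_iris) == sum(len(x.entries) for x in extracts)


def test_reloading_the_same_extracts_is_idempotent(store, library):
    rng = random.Random(123)
    extracts = [random_extract(rng, library) for _ in range(10)]
    load_extracts(extracts, store, library)
    n = len(store.instances)
    again = load_extracts(extracts, store, library)
    assert len(store.instances) == n
    assert again.triples_added == 0


def test_every_instance_is_transitively_an_rm_entry(store, library):
    rng = random.Random(7)
    load_extracts([random_extract(rng, library) for _ in range(10)], store, library)
    untyped = list(
        store.ds.query(
            """
            SELECT ?i WHERE {
              GRAPH <http://ehrbridge.org/graph/instances> { ?i a ?cls . }
              ?cls map:archetypeId ?aid .
              FILTER NOT EXISTS { ?cls rdfs:subClassOf+ iso13606:Entry . }
            }
            """,
            initNs={"map": MAP, "iso13606": ISO},
        )
    )
    assert untyped == []


def test_literal_datatypes_match_the_declared_element_kind(store, library):
    """Every assertion's literal type agrees with the archetype's kind."""
    rng = random.Random(11)
    load_extracts([random_extract(rng, library) for _ in range(10)], store, library)
    kind_of = {}  # property IRI -> declared kind
    for archetype in library:
        from ehrbridge.ontology import element_property

        for el in archetype.entry.elements:
            kind_of[element_property(archetype, el.node_id)] = el.kind
    checked = 0
    for s, p, o in store.instances:
        kind = kind_of.get(p)
        if kind is None:
            continue
        if kind in STRUCTURED_KINDS:
            assert isinstance(o, URIRef)
        elif kind is ValueKind.DATE_TIME:
            assert isinstance(o, Literal) and o.datatype == XSD.dateTime
        elif kind is ValueKind.BOOLEAN:
            assert isinstance(o, Literal) and o.datatype == XSD.boolean
        else:
            assert isinstance(o, Literal) and o.datatype in (None, XSD.string)
        checked += 1
    assert checked > 0


def test_unknown_archetype_rolls_back_the_whole_batch(library):
    bare = TripleGraph()  # no concept ontologies built
    rng = random.Random(1)
    with pytest.raises(LoadError, match="no concept ontology"):
        load_extracts([random_extract(rng, library)], bare, library)
    assert len(bare.instances) == 0


def test_partial_failure_loads_nothing(store, library):
    rng = random.Random(2)
    good = random_extract(rng, library)
    bad = good.model_copy(
        update={
            "entries": [
                good.entries[0].model_copy(
                    update={"archetype_id": "EHRB-ENTRY.diagnosis.v1", "values": {}}
                )
            ]
        }
    )
    before = len(store.instances)
    with pytest.raises(LoadError):
        load_extracts([good, bad], store, library)
    assert len(store.instances) == before
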