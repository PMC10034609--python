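"""Source rows → validated entries → extract XML, and back."""

import random

import pandas as pd
import pytest

from ehrbridge.extracts import (
    EHRExtract,
    Entry,
    ExtractConfig,
    ExtractError,
    MappingError,
    MappingSpec,
    Provenance,
    build_extracts,
    parse_extract,
    serialize_extract,
    validate_extract,
)
from ehrbridge.pipeline import builtin_extract_mappings
from ehrbridge.rm import DataValue, ValueKind

from conftest import random_extract


def _diagnosis_mapping():
    return next(
        m for m in builtin_extract_mappings() if m.archetype_id.endswith("diagnosis.v1")
    )


def _diagnosis_row(**overrides):
    row = {
        "diagnosis_id": "DXREC000001",
        "episode_id": "EP000123",
        "patient_id": "PAT00001",
        "local_dx_code": "DX011",
        "recorded_datetime": "2020-03-01 10:30:00",
        "source": "HIS-TEST",
    }
    row.update(overrides)
    return row


def _build_diagnoses(rows, library, terminology, categories):
    source = {"diagnoses": pd.DataFrame(rows)}
    return build_extracts(
        source,
        _diagnosis_mapping(),
        library.by_concept("diagnosis"),
        terminology,
        categories,
    )


def test_glaucoma_source_row_yields_one_normalized_entry(
    library, terminology_table, category_rules
):
    """A local glaucoma code becomes an ICD-10-CM H40.9 entry with its
    record datetime and episode identifier."""
    extracts, report = _build_diagnoses(
        [_diagnosis_row()], library, terminology_table, category_rules
    )
    assert report.rows_seen == 1 and report.entries_built == 1 and not report.quarantined
    [extract] = extracts
    [entry] = extract.entries
    dx = entry.values["diagnosis"]
    assert (dx.code, dx.code_system) == ("H40.9", "ICD-10-CM")
    assert dx.display.lower() == "unspecified glaucoma"
    assert entry.values["episode_id"].id_value == "EP000123"
    assert entry.values["diagnosis_datetime"].timestamp == "2020-03-01T10:30:00+01:00"
    assert extract.patient_id == "PAT00001"


def test_empty_source_table_builds_nothing(library, terminology_table, category_rules):
    empty = pd.DataFrame(columns=list(_diagnosis_row().keys()))
    extracts, report = build_extracts(
        {"diagnoses": empty},
        _diagnosis_mapping(),
        library.by_concept("diagnosis"),
        terminology_table,
        category_rules,
    )
    assert extracts == [] and report.rows_seen == 0 and not report.quarantined


def test_row_count_conservation_with_quarantine(
    library, terminology_table, category_rules
):
    """rows = entries + quarantined, exactly, and reasons name the element."""
    rows = [_diagnosis_row(diagnosis_id=f"DXREC{i:06d}") for i in range(20)]
    rows[3]["local_dx_code"] = ""  # mandatory element unpopulated
    rows[11]["recorded_datetime"] = ""  # mandatory element unpopulated
    extracts, report = _build_diagnoses(rows, library, terminology_table, category_rules)
    n_entries = sum(len(x.entries) for x in extracts)
    assert report.rows_seen == 20
    assert n_entries == report.entries_built == 18
    assert len(report.quarantined) == 2
    assert report.conserved
    reasons = dict(report.quarantined)
    assert "diagnosis" in reasons[3] and "diagnosis_datetime" in reasons[11]


def test_mapping_to_missing_column_fails_before_any_row(
    library, terminology_table, category_rules
):
    mapping = _diagnosis_mapping().model_copy(
        update={
            "elements": {
                **_diagnosis_mapping().elements,
                "diagnosis": _diagnosis_mapping().elements["diagnosis"].model_copy(
                    update={"column": "no_such_column"}
                ),
            }
        }
    )
    with pytest.raises(MappingError, match="no_such_column"):
        build_extracts(
            {"diagnoses": pd.DataFrame([_diagnosis_row()])},
            mapping,
            library.by_concept("diagnosis"),
            terminology_table,
            category_rules,
        )


def test_mandatory_binding_missing_is_a_mapping_error(library):
    mapping = _diagnosis_mapping()
    trimmed = mapping.model_copy(
        update={"elements": {k: v for k, v in mapping.elements.items() if k != "diagnosis"}}
    )
    with pytest.raises(MappingError, match="diagnosis"):
        trimmed.validate_against(
            library.by_concept("diagnosis"), list(_diagnosis_row().keys())
        )


def test_serialized_extract_carries_code_and_system(
    library, terminology_table, category_rules
):
    extracts, _ = _build_diagnoses(
        [_diagnosis_row()], library, terminology_table, category_rules
    )
    xml = serialize_extract(extracts[0], library)
    assert b'code="H40.9"' in xml
    assert b'code-system="ICD-10-CM"' in xml
    assert validate_extract(xml, library).ok


def test_optional_elements_are_omitted_not_emitted_empty(library):
    episode = library.by_concept("episode")
    entry = Entry(
        archetype_id=episode.archetype_id,
        values={
            "episode_id": DataValue.identifier("E1"),
            "patient_id": DataValue.identifier("P1"),
            "episode_type": DataValue.coded_text("HOSP", "local"),
            "admission_datetime": DataValue.date_time("2020-05-01T08:00:00+02:00"),
            "source": DataValue.simple_text("HIS"),
        },
    )
    extract = EHRExtract(
        extract_id="episode-P1",
        patient_id="P1",
        provenance=Provenance(source="HIS", extracted_at="2022-02-15T00:00:00+01:00"),
        entries=[entry],
    )
    xml = serialize_extract(extract, library)
    assert b"discharge_datetime" not in xml and b"discharge_type" not in xml
    assert parse_extract(xml) == extract


def test_round_trip_identity_over_many_random_extracts(library):
    rng = random.Random(20200217)
    for _ in range(1000):
        extract = random_extract(rng, library)
        assert parse_extract(serialize_extract(extract, library)) == extract


def test_invalid_extract_is_refused_with_violations(library):
    entry = Entry(
        archetype_id="EHRB-ENTRY.diagnosis.v1",
        values={"patient_id": DataValue.identifier("P1")},  # mandatory elements missing
    )
    extract = EHRExtract(
        extract_id="diagnosis-P1",
        patient_id="P1",
        provenance=Provenance(source="HIS", extracted_at="2022-02-15T00:00:00+01:00"),
        entries=[entry],
    )
    with pytest.raises(ExtractError, match="mandatory element not populated"):
        serialize_extract(extract, library)


def test_validation_reports_exactly_the_removed_element(library):
    rng = random.Random(5)
    extract = random_extract(rng, library)
    xml = serialize_extract(extract, library)
    assert validate_extract(xml, library).ok
    # drop one mandatory element from the model and re-check
    entry = extract.entries[0]
    archetype = library.get(entry.archetype_id)
    victim = next(el.node_id for el in archetype.entry.elements if el.mandatory)
    broken = entry.model_copy(
        update={"values": {k: v for k, v in entry.values.items() if k != victim}}
    )
    from ehrbridge.extracts import validate_extract_model

    report = validate_extract_model(
        extract.model_copy(update={"entries": [broken] + extract.entries[1:]}), library
    )
    assert len(report) == 1
    assert victim in report.violations[0].path


def test_unknown_archetype_in_extract_is_reported_not_raised(library):
    entry = Entry(archetype_id="EHRB-ENTRY.unknown.v1", values={})
    extract = EHRExtract(
        extract_id="x-P1",
        patient_id="P1",
        provenance=Provenance(source="HIS", extracted_at="2022-02-15T00:00:00+01:00"),
        entries=[entry],
    )
    from ehrbridge.extracts import validate_extract_model

    report = validate_extract_model(extract, library)
    assert len(report) == 1 and "unknown archetype_id" in report.violations[0].message


def test_rebuild_from_same_source_is_byte_identical(
    library, terminology_table, category_rules, small_source
):
    mapping = _diagnosis_mapping()
    archetype = library.by_concept("diagnosis")
    config = ExtractConfig()
    runs = []
    for _ in range(2):
        extracts, _ = build_extracts(
            small_source, mapping, archetype, terminology_table, category_rules, config
        )
        runs.append(b"".join(serialize_extract(x, library) for x in extracts))
    assert runs[0] == runs[1]
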