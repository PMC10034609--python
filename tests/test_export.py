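"""OMOP table export: query generation, derivation, pseudonymization."""

import pandas as pd
import pytest

from ehrbridge.export import (
    ConfigurationError,
    ExportConfig,
    export_all,
    generate_query,
    pseudonymize,
    run_table_query,
)
from ehrbridge.omop_schema import CLINICAL_TABLES, SchemaError, default_schema
from ehrbridge.ontology import TripleGraph, load_omop_mapping

from conftest import SALT


def _read(pipeline, table):
    return pd.read_csv(
        pipeline.export_dir / f"{table}.csv", dtype=str, keep_default_na=False
    )


def test_person_query_projects_every_schema_column(pipeline):
    """Unmapped columns must still appear in the SELECT clause."""
    query = generate_query("Person", pipeline.store)
    select = query.splitlines()[2]
    assert select.startswith("SELECT ")
    for column in default_schema().columns("Person"):
        assert f"?{column}" in select
    # race_concept_id has no mapped property: present in SELECT, absent below
    assert "race_concept_id" not in query.split("WHERE", 1)[1]


def test_person_rows_equal_patient_instances(pipeline):
    df = run_table_query("Person", pipeline.store)
    n_instances = pipeline.export.manifest["instances"]["EHRB-ENTRY.patient.v1"]
    assert len(df) == n_instances
    assert len(_read(pipeline, "Person")) == n_instances


def test_unknown_table_error_lists_the_supported_tables():
    with pytest.raises(SchemaError, match="Condition_occurrence"):
        generate_query("No_such_table", TripleGraph())


def test_default_export_emits_exactly_the_ten_clinical_tables(pipeline):
    csvs = {p.stem for p in pipeline.export_dir.glob("*.csv")} - {"integrity_report"}
    assert csvs == set(CLINICAL_TABLES)
    assert set(pipeline.export.tables) == set(CLINICAL_TABLES)


def test_empty_store_exports_header_only_tables(library, tmp_path):
    store = TripleGraph()
    store.build_layers(library, load_omop_mapping())
    result = export_all(store, pseudonym_salt=SALT, out_dir=tmp_path)
    schema = default_schema()
    for table in CLINICAL_TABLES:
        text = (tmp_path / f"{table}.csv").read_bytes().decode("utf-8")
        header, rest = text.split("\r\n", 1)
        assert header.split(",") == schema.columns(table)
        assert rest.strip() == ""
    assert len(result.integrity) == 0


def test_referential_integrity_no_orphans(pipeline):
    assert pipeline.export.manifest["integrity_issues"] == 0
    persons = set(_read(pipeline, "Person")["person_id"])
    visits = set(_read(pipeline, "Visit_occurrence")["visit_occurrence_id"])
    for table in CLINICAL_TABLES:
        df = _read(pipeline, table)
        if table != "Person" and "person_id" in df.columns:
            assert set(df["person_id"]) - {""} <= persons, table
    vd = _read(pipeline, "Visit_detail")
    assert set(vd["visit_occurrence_id"]) - {""} <= visits


def test_pseudonymization_is_deterministic_and_keyed():
    assert pseudonymize("PAT00001", "salt-a") == pseudonymize("PAT00001", "salt-a")
    assert pseudonymize("PAT00001", "salt-a") != pseudonymize("PAT00001", "salt-b")
    assert pseudonymize("PAT00001", "salt-a") != pseudonymize("PAT00002", "salt-a")
    with pytest.raises(ConfigurationError):
        pseudonymize("PAT00001", "")
    with pytest.raises(ValueError):
        pseudonymize("", "salt")


def test_pseudonyms_collision_free_at_ten_thousand_ids():
    ids = [f"PAT{i:07d}" for i in range(10_000)]
    pseudonyms = {pseudonymize(i, "collision-scan") for i in ids}
    assert len(pseudonyms) == len(ids)


def test_no_source_identifier_appears_in_any_exported_csv(pipeline, default_source):
    identifiers = (
        list(default_source["patients"]["patient_id"])
        + list(default_source["episodes"]["episode_id"])
        + list(default_source["diagnoses"]["diagnosis_id"].head(50))
        + list(default_source["administrations"]["administration_id"].head(50))
    )
    for path in pipeline.export_dir.glob("*.csv"):
        text = path.read_text()
        for ident in identifiers:
            assert ident not in text, (path.name, ident)


def test_reexport_same_store_and_salt_is_byte_identical(pipeline, tmp_path):
    export_all(pipeline.store, pseudonym_salt=SALT, out_dir=tmp_path)
    for path in sorted(pipeline.export_dir.glob("*.csv")):
        assert (tmp_path / path.name).read_bytes() == path.read_bytes(), path.name


def test_concept_ids_default_to_zero_and_dates_follow_datetimes(pipeline):
    co = _read(pipeline, "Condition_occurrence")
    assert (co["condition_concept_id"] == "0").all()
    assert (co["condition_start_date"] == co["condition_start_datetime"].str[:10]).all()
    person = _read(pipeline, "Person")
    assert (person["year_of_birth"] == person["birth_datetime"].str[:4]).all()


def test_cross_representation_conservation(pipeline):
    """Instances per archetype equal their mapped table's rows, with the
    drug archetypes summing into Drug_exposure and procedure rows split
    between Device_exposure and the logged exclusions."""
    inst = pipeline.export.manifest["instances"]
    tables = pipeline.export.manifest["tables"]
    assert tables["Person"] == inst["EHRB-ENTRY.patient.v1"]
    assert tables["Visit_occurrence"] == inst["EHRB-ENTRY.episode.v1"]
    assert tables["Condition_occurrence"] == inst["EHRB-ENTRY.diagnosis.v1"]
    assert tables["Visit_detail"] == inst["EHRB-ENTRY.unit_movement.v1"]
    assert tables["Observation"] == inst["EHRB-ENTRY.llst.v1"]
    assert tables["Drug_exposure"] == (
        inst["EHRB-ENTRY.administered_medication.v1"]
        + inst["EHRB-ENTRY.prescribed_medication.v1"]
        + inst["EHRB-ENTRY.cumulative_drug_dose.v1"]
    )
    assert tables["Measurement"] == (
        inst["EHRB-ENTRY.clinical_observation.v1"]
        + inst["EHRB-ENTRY.laboratory_observation.v1"]
    )
    excluded = sum(e["rows"] for e in pipeline.export.manifest["excluded"])
    assert tables["Device_exposure"] + excluded == inst["EHRB-ENTRY.procedure.v1"]


def test_death_rows_match_death_discharges(pipeline, default_source):
    episodes = default_source["episodes"]
    dead_patients = set(
        episodes.loc[episodes["discharge_type"] == "DEATH", "patient_id"]
    )
    assert pipeline.export.manifest["tables"]["Death"] == len(dead_patients)


def test_observation_period_spans_every_person_with_events(pipeline):
    op = _read(pipeline, "Observation_period")
    assert len(op) == pipeline.export.manifest["tables"]["Person"]
    assert (
        op["observation_period_start_date"] <= op["observation_period_end_date"]
    ).all()


def test_procedure_occurrence_behind_config_flag(pipeline, tmp_path):
    result = export_all(
        pipeline.store,
        pseudonym_salt=SALT,
        out_dir=tmp_path,
        config=ExportConfig(include_procedure_occurrence=True),
    )
    assert "Procedure_occurrence" in result.tables
    inst = result.manifest["instances"]["EHRB-ENTRY.procedure.v1"]
    assert (
        result.manifest["tables"]["Procedure_occurrence"]
        + result.manifest["tables"]["Device_exposure"]
        == inst
    )
    assert result.manifest["excluded"] == []
    po = result.tables["Procedure_occurrence"]
    assert (po["modifier_source_value"] == "").all()  # routing carrier cleared
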