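"""OMOP CDM clinical-table schemas, pinned to the v5.4 column names.

The default export covers the ten standardized clinical-data tables:
Condition_occurrence, Death, Device_exposure, Drug_exposure, Measurement,
Observation, Observation_period, Person, Visit_detail and Visit_occurrence.
Procedure_occurrence is additionally defined so it can be emitted behind a
configuration flag. Declared cell types are: integer, string, date,
datetime, decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

Column = Tuple[str, str]  # (name, declared type)

_SCHEMAS: Dict[str, List[Column]] = {
    "Person": [
        ("person_id", "integer"),
        ("gender_concept_id", "integer"),
        ("year_of_birth", "integer"),
        ("month_of_birth", "integer"),
        ("day_of_birth", "integer"),
        ("birth_datetime", "datetime"),
        ("race_concept_id", "integer"),
        ("ethnicity_concept_id", "integer"),
        ("location_id", "integer"),
        ("provider_id", "integer"),
        ("care_site_id", "integer"),
        ("person_source_value", "string"),
        ("gender_source_value", "string"),
        ("gender_source_concept_id", "integer"),
        ("race_source_value", "string"),
        ("race_source_concept_id", "integer"),
        ("ethnicity_source_value", "string"),
        ("ethnicity_source_concept_id", "integer"),
    ],
    "Visit_occurrence": [
        ("visit_occurrence_id", "integer"),
        ("person_id", "integer"),
        ("visit_concept_id", "integer"),
        ("visit_start_date", "date"),
        ("visit_start_datetime", "datetime"),
        ("visit_end_date", "date"),
        ("visit_end_datetime", "datetime"),
        ("visit_type_concept_id", "integer"),
        ("provider_id", "integer"),
        ("care_site_id", "integer"),
        ("visit_source_value", "string"),
        ("visit_source_concept_id", "integer"),
        ("admitted_from_concept_id", "integer"),
        ("admitted_from_source_value", "string"),
        ("discharged_to_concept_id", "integer"),
        ("discharged_to_source_value", "string"),
        ("preceding_visit_occurrence_id", "integer"),
    ],
    "Visit_detail": [
        ("visit_detail_id", "integer"),
        ("person_id", "integer"),
        ("visit_detail_concept_id", "integer"),
        ("visit_detail_start_date", "date"),
        ("visit_detail_start_datetime", "datetime"),
        ("visit_detail_end_date", "date"),
        ("visit_detail_end_datetime", "datetime"),
        ("visit_detail_type_concept_id", "integer"),
        ("provider_id", "integer"),
        ("care_site_id", "integer"),
        ("visit_detail_source_value", "string"),
        ("visit_detail_source_concept_id", "integer"),
        ("admitted_from_concept_id", "integer"),
        ("admitted_from_source_value", "string"),
        ("discharged_to_concept_id", "integer"),
        ("discharged_to_source_value", "string"),
        ("preceding_visit_detail_id", "integer"),
        ("parent_visit_detail_id", "integer"),
        ("visit_occurrence_id", "integer"),
    ],
    "Condition_occurrence": [
        ("condition_occurrence_id", "integer"),
        ("person_id", "integer"),
        ("condition_concept_id", "integer"),
        ("condition_start_date", "date"),
        ("condition_start_datetime", "datetime"),
        ("condition_end_date", "date"),
        ("condition_end_datetime", "datetime"),
        ("condition_type_concept_id", "integer"),
        ("condition_status_concept_id", "integer"),
        ("stop_reason", "string"),
        ("provider_id", "integer"),
        ("visit_occurrence_id", "integer"),
        ("visit_detail_id", "integer"),
        ("condition_source_value", "string"),
        ("condition_source_concept_id", "integer"),
        ("condition_status_source_value", "string"),
    ],
    "Drug_exposure": [
        ("drug_exposure_id", "integer"),
        ("person_id", "integer"),
        ("drug_concept_id", "integer"),
        ("drug_exposure_start_date", "date"),
        ("drug_exposure_start_datetime", "datetime"),
        ("drug_exposure_end_date", "date"),
        ("drug_exposure_end_datetime", "datetime"),
        ("verbatim_end_date", "date"),
        ("drug_type_concept_id", "integer"),
        ("stop_reason", "string"),
        ("refills", "integer"),
        ("quantity", "decimal"),
        ("days_supply", "integer"),
        ("sig", "string"),
        ("route_concept_id", "integer"),
        ("lot_number", "string"),
        ("provider_id", "integer"),
        ("visit_occurrence_id", "integer"),
        ("visit_detail_id", "integer"),
        ("drug_source_value", "string"),
        ("drug_source_concept_id", "integer"),
        ("route_source_value", "string"),
        ("dose_unit_source_value", "string"),
    ],
    "Measurement": [
        ("measurement_id", "integer"),
        ("person_id", "integer"),
        ("measurement_concept_id", "integer"),
        ("measurement_date", "date"),
        ("measurement_datetime", "datetime"),
        ("measurement_time", "string"),
        ("measurement_type_concept_id", "integer"),
        ("operator_concept_id", "integer"),
        ("value_as_number", "decimal"),
        ("value_as_concept_id", "integer"),
        ("unit_concept_id", "integer"),
        ("range_low", "decimal"),
        ("range_high", "decimal"),
        ("provider_id", "integer"),
        ("visit_occurrence_id", "integer"),
        ("visit_detail_id", "integer"),
        ("measurement_source_value", "string"),
        ("measurement_source_concept_id", "integer"),
        ("unit_source_value", "string"),
        ("unit_source_concept_id", "integer"),
        ("value_source_value", "string"),
        ("measurement_event_id", "integer"),
        ("meas_event_field_concept_id", "integer"),
    ],
    "Observation": [
        ("observation_id", "integer"),
        ("person_id", "integer"),
        ("observation_concept_id", "integer"),
        ("observation_date", "date"),
        ("observation_datetime", "datetime"),
        ("observation_type_concept_id", "integer"),
        ("value_as_number", "decimal"),
        ("value_as_string", "string"),
        ("value_as_concept_id", "integer"),
        ("qualifier_concept_id", "integer"),
        ("unit_concept_id", "integer"),
        ("provider_id", "integer"),
        ("visit_occurrence_id", "integer"),
        ("visit_detail_id", "integer"),
        ("observation_source_value", "string"),
        ("observation_source_concept_id", "integer"),
        ("unit_source_value", "string"),
        ("qualifier_source_value", "string"),
        ("value_source_value", "string"),
        ("observation_event_id", "integer"),
        ("obs_event_field_concept_id", "integer"),
    ],
    "Observation_period": [
        ("observation_period_id", "integer"),
        ("person_id", "integer"),
        ("observation_period_start_date", "date"),
        ("observation_period_end_date", "date"),
        ("period_type_concept_id", "integer"),
    ],
    "Death": [
        ("person_id", "integer"),
        ("death_date", "date"),
        ("death_datetime", "datetime"),
        ("death_type_concept_id", "integer"),
        ("cause_concept_id", "integer"),
        ("cause_source_value", "string"),
        ("cause_source_concept_id", "integer"),
    ],
    "Device_exposure": [
        ("device_exposure_id", "integer"),
        ("person_id", "integer"),
        ("device_concept_id", "integer"),
        ("device_exposure_start_date", "date"),
        ("device_exposure_start_datetime", "datetime"),
        ("device_exposure_end_date", "date"),
        ("device_exposure_end_datetime", "datetime"),
        ("device_type_concept_id", "integer"),
        ("unique_device_id", "string"),
        ("production_id", "string"),
        ("quantity", "integer"),
        ("provider_id", "integer"),
        ("visit_occurrence_id", "integer"),
        ("visit_detail_id", "integer"),
        ("device_source_value", "string"),
        ("device_source_concept_id", "integer"),
        ("unit_concept_id", "integer"),
        ("unit_source_value", "string"),
        ("unit_source_concept_id", "integer"),
    ],
    "Procedure_occurrence": [
        ("procedure_occurrence_id", "integer"),
        ("person_id", "integer"),
        ("procedure_concept_id", "integer"),
        ("procedure_date", "date"),
        ("procedure_datetime", "datetime"),
        ("procedure_end_date", "date"),
        ("procedure_end_datetime", "datetime"),
        ("procedure_type_concept_id", "integer"),
        ("modifier_concept_id", "integer"),
        ("quantity", "integer"),
        ("provider_id", "integer"),
        ("visit_occurrence_id", "integer"),
        ("visit_detail_id", "integer"),
        ("procedure_source_value", "string"),
        ("procedure_source_concept_id", "integer"),
        ("modifier_source_value", "string"),
    ],
}

#: The ten clinical tables of the default export, in emission order.
CLINICAL_TABLES = (
    "Condition_occurrence",
    "Death",
    "Device_exposure",
    "Drug_exposure",
    "Measurement",
    "Observation",
    "Observation_period",
    "Person",
    "Visit_detail",
    "Visit_occurrence",
)


class SchemaError(KeyError):
    pass


@dataclass(frozen=True)
class OmopSchema:
    """Table name -> ordered typed column list for the supported tables."""

    tables: Dict[str, List[Column]]

    def columns(self, table: str) -> List[str]:
        return [c for c, _ in self.table(table)]

    def table(self, table: str) -> List[Column]:
        if table not in self.tables:
            raise SchemaError(
                f"unknown table {table!r}; supported tables: {sorted(self.tables)}"
            )
        return self.tables[table]

    def has_column(self, table: str, column: str) -> bool:
        return table in self.tables and column in dict(self.tables[table])

    def column_type(self, table: str, column: str) -> str:
        return dict(self.table(table))[column]


def default_schema() -> OmopSchema:
    return OmopSchema(tables={t: list(cols) for t, cols in _SCHEMAS.items()})
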