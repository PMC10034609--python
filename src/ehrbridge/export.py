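"""OMOP CDM table export: generated SPARQL queries + tabular post-pass.

For each clinical table, a SPARQL query is generated from the layer-3
mapping: one projected variable per schema column (columns with no mapped
property stay unbound and are emitted as empty cells), with value
navigation following the reference-model typing (coded text through its
code value, quantities through magnitude and units, identifiers through
their id value). Transformations that do not fit the graph query — date
derivation, concept_id defaults, pseudonymization, the three derived
tables — run in a deterministic tabular post-pass.

Derived tables (no archetype feeds them directly):

* ``Observation_period`` — per person, the span from earliest to latest
  event date across all exported events.
* ``Death`` — one row per person from episodes whose discharge disposition
  carries the configured death code (latest such episode wins).
* ``Device_exposure`` — procedure rows whose device flag is set, re-shaped
  into the device schema.

All person/visit/record identifiers are pseudonymized with a keyed one-way
transform; re-export from the same store and salt is byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import hmac
import json
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict
from rdflib import Graph, RDF, URIRef
from rdflib.namespace import OWL

from ehrbridge.omop_schema import CLINICAL_TABLES, OmopSchema, SchemaError, default_schema
from ehrbridge.ontology import ISO, MAP, OMOP, TripleGraph
from ehrbridge.rm import ValueKind


class ConfigurationError(ValueError):
    pass


class ExportConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    include_procedure_occurrence: bool = False
    death_discharge_value: str = "DEATH"


# ---------------------------------------------------------------------------
# pseudonymization


def pseudonymize(identifier: str, salt: str) -> str:
    """Deterministic keyed one-way pseudonym (decimal digits of an HMAC).

    Stable across tables within one export run; the 63-bit keyed digest
    makes collisions vanishingly unlikely at realistic cohort sizes.
    """
    if not salt:
        raise ConfigurationError("pseudonymization salt must be non-empty")
    if not identifier:
        raise ValueError("identifier must be non-empty")
    digest = hmac.new(salt.encode("utf-8"), str(identifier).encode("utf-8"), hashlib.sha256)
    return str(int.from_bytes(digest.digest()[:8], "big") & (2**63 - 1))


def _pseudonym_hex(identifier: str, salt: str) -> str:
    digest = hmac.new(salt.encode("utf-8"), str(identifier).encode("utf-8"), hashlib.sha256)
    return digest.hexdigest()[:16]


# ---------------------------------------------------------------------------
# query generation

#: structured-value leaf property per (value kind, mapped part)
_LEAF = {
    (ValueKind.CODED_TEXT, "value"): "iso13606:codeValue",
    (ValueKind.CODED_TEXT, "display"): "iso13606:displayName",
    (ValueKind.QUANTITY, "value"): "iso13606:magnitude",
    (ValueKind.QUANTITY, "units"): "iso13606:units",
    (ValueKind.IDENTIFIER, "value"): "iso13606:idValue",
}

_PART_PREDICATES = {
    "value": MAP.mapsToColumn,
    "units": MAP.unitsMapToColumn,
    "display": MAP.displayMapsToColumn,
}

_PREFIXES = (
    "PREFIX iso13606: <http://ehrbridge.org/ns/iso13606#>\n"
    "PREFIX map: <http://ehrbridge.org/ns/map#>\n"
)


def _union_graph(store: TripleGraph | Graph) -> Graph:
    if isinstance(store, TripleGraph):
        return store.ds
    return store


def _table_bindings(
    g: Graph, table: str
) -> List[Tuple[URIRef, List[Tuple[URIRef, str, ValueKind, str]]]]:
    """Per concept class mapped to *table*: (prop, column, kind, part) list."""
    out = []
    for cls in sorted(g.subjects(MAP.mapsToTable, OMOP[table])):
        bindings = []
        for part, predicate in _PART_PREDICATES.items():
            for prop, col in g.subject_objects(predicate):
                col_str = str(col)
                prefix = f"{OMOP}{table}."
                if not col_str.startswith(prefix):
                    continue
                # the property must belong to this concept's archetype
                from rdflib import RDFS

                if (prop, RDFS.domain, cls) not in g:
                    continue
                kind_lit = g.value(prop, MAP.valueKind)
                kind = ValueKind(str(kind_lit)) if kind_lit is not None else ValueKind.SIMPLE_TEXT
                bindings.append((prop, col_str[len(prefix):], kind, part))
        bindings.sort(key=lambda b: (b[1], str(b[0])))
        out.append((cls, bindings))
    return out


def generate_query(
    table: str,
    layer3: TripleGraph | Graph,
    schema: Optional[OmopSchema] = None,
) -> str:
    """Generate the SPARQL query exporting one OMOP table.

    The projection covers every schema column of the table; columns with no
    mapped property remain unbound and yield empty cells. When several
    archetypes feed one table, their blocks are combined with UNION.
    """
    schema = schema or default_schema()
    if table not in schema.tables:
        raise SchemaError(
            f"unknown table {table!r}; supported tables: {sorted(schema.tables)}"
        )
    g = _union_graph(layer3)
    columns = schema.columns(table)
    blocks = []
    for cls, bindings in _table_bindings(g, table):
        lines = [f"    ?__inst a <{cls}> ."]
        node_vars: Dict[URIRef, str] = {}
        for i, (prop, column, kind, part) in enumerate(bindings):
            if column not in columns:
                continue
            if kind in _dict_structured():
                node = node_vars.setdefault(prop, f"?__node{len(node_vars)}")
                leaf = _LEAF[(kind, part)]
                lines.append(
                    f"    OPTIONAL {{ ?__inst <{prop}> {node} . {node} {leaf} ?{column} . }}"
                )
            else:
                lines.append(f"    OPTIONAL {{ ?__inst <{prop}> ?{column} . }}")
        blocks.append("  {\n" + "\n".join(lines) + "\n  }")
    select = " ".join(f"?{c}" for c in columns)
    if not blocks:
        # no archetype feeds this table directly; empty-result query with
        # the full projection so the header-only table can still be emitted
        where = "  FILTER(false)"
    else:
        where = "\n  UNION\n".join(blocks)
    return f"{_PREFIXES}SELECT {select}\nWHERE {{\n{where}\n}}\n"


def _dict_structured():
    return {ValueKind.CODED_TEXT, ValueKind.QUANTITY, ValueKind.IDENTIFIER}


def _cell(value) -> str:
    if value is None:
        return ""
    py = value.toPython() if hasattr(value, "toPython") else value
    if isinstance(py, bool):
        return "true" if py else "false"
    if isinstance(py, Decimal):
        return str(py)
    return str(py)


def run_table_query(
    table: str, store: TripleGraph, schema: Optional[OmopSchema] = None
) -> pd.DataFrame:
    """Execute the generated query; all cells come back as strings."""
    schema = schema or default_schema()
    query = generate_query(table, store, schema)
    columns = schema.columns(table)
    result = store.ds.query(query)
    rows = [[_cell(v) for v in row] for row in result]
    return pd.DataFrame(rows, columns=columns, dtype=str)


# ---------------------------------------------------------------------------
# post-pass helpers

_ID_COLUMNS = {
    "person_id",
    "visit_occurrence_id",
    "visit_detail_id",
    "condition_occurrence_id",
    "drug_exposure_id",
    "measurement_id",
    "observation_id",
    "observation_period_id",
    "device_exposure_id",
    "procedure_occurrence_id",
    "preceding_visit_occurrence_id",
    "preceding_visit_detail_id",
    "parent_visit_detail_id",
    "measurement_event_id",
    "observation_event_id",
}

_HEX_PSEUDONYM_COLUMNS = {"person_source_value"}


def _date_of(iso_datetime: str) -> str:
    return iso_datetime[:10] if iso_datetime else ""


def _postpass(df: pd.DataFrame, table: str, schema: OmopSchema, salt: str) -> pd.DataFrame:
    df = df.copy()
    columns = schema.columns(table)
    for c in columns:
        if c not in df.columns:
            df[c] = ""
    df = df[columns].fillna("")
    for c in columns:
        if c.endswith("concept_id"):
            df[c] = "0"
        elif c.endswith("_date"):
            dt_col = c[: -len("_date")] + "_datetime"
            if dt_col in df.columns:
                df[c] = df[dt_col].map(_date_of)
        if c in _ID_COLUMNS:
            df[c] = df[c].map(lambda v: pseudonymize(v, salt) if v else "")
        elif c in _HEX_PSEUDONYM_COLUMNS:
            df[c] = df[c].map(lambda v: _pseudonym_hex(v, salt) if v else "")
    if table == "Person":
        df["year_of_birth"] = df["birth_datetime"].str.slice(0, 4)
        df["month_of_birth"] = df["birth_datetime"].str.slice(5, 7).str.lstrip("0")
        df["day_of_birth"] = df["birth_datetime"].str.slice(8, 10).str.lstrip("0")
    # stable row ordering by pseudonymized keys (whole-row tie-break)
    if len(df):
        df = df.sort_values(by=list(df.columns), kind="mergesort").reset_index(drop=True)
    return df


@dataclass
class ExportResult:
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    integrity: pd.DataFrame = field(default_factory=pd.DataFrame)
    manifest: Dict = field(default_factory=dict)
    excluded: List[Dict] = field(default_factory=list)


def _instance_counts(store: TripleGraph) -> Dict[str, int]:
    """Instances per archetype id, read from the store."""
    counts: Dict[str, int] = {}
    g = store.ds
    for cls, aid in g.subject_objects(MAP.archetypeId):
        n = sum(1 for _ in store.instances.subjects(RDF.type, cls))
        counts[str(aid)] = n
    return counts


def _derive_death(visit_raw: pd.DataFrame, config: ExportConfig) -> pd.DataFrame:
    cols = [
        "person_id",
        "death_date",
        "death_datetime",
        "death_type_concept_id",
        "cause_concept_id",
        "cause_source_value",
        "cause_source_concept_id",
    ]
    deaths = visit_raw[
        visit_raw["discharged_to_source_value"] == config.death_discharge_value
    ].copy()
    if deaths.empty:
        return pd.DataFrame(columns=cols, dtype=str)
    deaths["__when"] = deaths["visit_end_datetime"].where(
        deaths["visit_end_datetime"] != "", deaths["visit_start_datetime"]
    )
    deaths = deaths.sort_values("__when").groupby("person_id", as_index=False).last()
    out = pd.DataFrame(
        {
            "person_id": deaths["person_id"],
            "death_date": deaths["__when"].map(_date_of),
            "death_datetime": deaths["__when"],
        }
    )
    for c in cols:
        if c not in out.columns:
            out[c] = ""
    return out[cols].astype(str)


_EVENT_DATE_COLUMNS = {
    "Visit_occurrence": ["visit_start_datetime", "visit_end_datetime"],
    "Visit_detail": ["visit_detail_start_datetime", "visit_detail_end_datetime"],
    "Condition_occurrence": ["condition_start_datetime"],
    "Drug_exposure": ["drug_exposure_start_datetime", "drug_exposure_end_datetime"],
    "Measurement": ["measurement_datetime"],
    "Observation": ["observation_datetime"],
    "Device_exposure": ["device_exposure_start_datetime"],
    "Procedure_occurrence": ["procedure_datetime"],
}


def _derive_observation_period(raw: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    cols = [
        "observation_period_id",
        "person_id",
        "observation_period_start_date",
        "observation_period_end_date",
        "period_type_concept_id",
    ]
    spans: Dict[str, Tuple[str, str]] = {}
    for table, date_cols in _EVENT_DATE_COLUMNS.items():
        df = raw.get(table)
        if df is None or df.empty:
            continue
        for _, row in df.iterrows():
            person = row.get("person_id", "")
            if not person:
                continue
            for c in date_cols:
                when = _date_of(str(row.get(c, "") or ""))
                if not when:
                    continue
                lo, hi = spans.get(person, (when, when))
                spans[person] = (min(lo, when), max(hi, when))
    rows = [
        {
            "observation_period_id": f"{person}::observation_period",
            "person_id": person,
            "observation_period_start_date": lo,
            "observation_period_end_date": hi,
            "period_type_concept_id": "0",
        }
        for person, (lo, hi) in sorted(spans.items())
    ]
    return pd.DataFrame(rows, columns=cols, dtype=str)


_DEVICE_FROM_PROCEDURE = {
    "procedure_occurrence_id": "device_exposure_id",
    "person_id": "person_id",
    "procedure_datetime": "device_exposure_start_datetime",
    "procedure_source_value": "device_source_value",
    "visit_occurrence_id": "visit_occurrence_id",
    "visit_detail_id": "visit_detail_id",
}


def export_all(
    store: TripleGraph,
    schema: Optional[OmopSchema] = None,
    pseudonym_salt: str = "",
    out_dir: Optional[Path | str] = None,
    config: Optional[ExportConfig] = None,
) -> ExportResult:
    """Export every clinical table from the instance store.

    Emits exactly one table per schema entry of the default table set
    (header-only when empty), an integrity report listing foreign-key
    orphans, and a manifest with per-table row counts, per-archetype
    instance counts and logged exclusions.
    """
    schema = schema or default_schema()
    config = config or ExportConfig()
    if not pseudonym_salt:
        raise ConfigurationError("pseudonym_salt must be provided")

    result = ExportResult()
    raw: Dict[str, pd.DataFrame] = {}
    for table in [
        "Person",
        "Visit_occurrence",
        "Visit_detail",
        "Condition_occurrence",
        "Drug_exposure",
        "Measurement",
        "Observation",
        "Procedure_occurrence",
    ]:
        raw[table] = run_table_query(table, store, schema)

    # route procedures: device-flagged rows feed Device_exposure
    proc = raw.pop("Procedure_occurrence")
    is_device = proc["modifier_source_value"] == "true"
    device_src = proc[is_device].copy()
    plain = proc[~is_device].copy()
    plain["modifier_source_value"] = ""  # routing carrier, not CDM content
    device = pd.DataFrame(
        {dst: device_src[src] for src, dst in _DEVICE_FROM_PROCEDURE.items()}
        if len(device_src)
        else {},
        dtype=str,
    )
    raw["Device_exposure"] = device
    if config.include_procedure_occurrence:
        raw["Procedure_occurrence"] = plain
    elif len(plain):
        result.excluded.append(
            {
                "table": "Procedure_occurrence",
                "rows": int(len(plain)),
                "reason": "procedure_occurrence table disabled in export config",
            }
        )

    raw["Death"] = _derive_death(raw["Visit_occurrence"], config)
    raw["Observation_period"] = _derive_observation_period(raw)

    tables = list(CLINICAL_TABLES)
    if config.include_procedure_occurrence:
        tables.append("Procedure_occurrence")
    for table in tables:
        df = raw.get(table, pd.DataFrame(dtype=str))
        result.tables[table] = _postpass(df, table, schema, pseudonym_salt)

    # referential integrity: person and visit foreign keys must resolve
    persons = set(result.tables["Person"]["person_id"])
    visits = set(result.tables["Visit_occurrence"]["visit_occurrence_id"])
    issues = []
    for table, df in result.tables.items():
        if table != "Person" and "person_id" in df.columns:
            for v in df.loc[~df["person_id"].isin(persons | {""}), "person_id"]:
                issues.append({"table": table, "column": "person_id", "value": v})
    vd = result.tables["Visit_detail"]
    for v in vd.loc[
        ~vd["visit_occurrence_id"].isin(visits | {""}), "visit_occurrence_id"
    ]:
        issues.append(
            {"table": "Visit_detail", "column": "visit_occurrence_id", "value": v}
        )
    result.integrity = pd.DataFrame(issues, columns=["table", "column", "value"])

    result.manifest = {
        "tables": {t: int(len(df)) for t, df in result.tables.items()},
        "instances": _instance_counts(store),
        "excluded": result.excluded,
        "integrity_issues": int(len(result.integrity)),
    }

    if out_dir is not None:
        write_export(result, out_dir)
    return result


def write_export(result: ExportResult, out_dir: Path | str) -> List[Path]:
    """Write one RFC 4180 CSV per table plus the report and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for table, df in result.tables.items():
        p = out / f"{table}.csv"
        _write_csv(df, p)
        written.append(p)
    _write_csv(result.integrity, out / "integrity_report.csv")
    (out / "export_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return written


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
        writer.writerow(list(df.columns))
        for row in df.itertuples(index=False):
            writer.writerow(["" if v is None else str(v) for v in row])
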