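# Methods

## The dual-model pipeline

`ehrbridge` converts tabular hospital source data into OMOP CDM research
tables by way of two intermediate representations: EN/ISO 13606-style EHR
extracts and a three-layer RDF ontology. The premise of the dual-model
approach is that the *reference model* (entry, element, data values) is
invariant, while the volatile clinical knowledge lives in *archetypes*; a new
concept therefore needs a new archetype and mapping configuration, not new
code.

### Reference-model subset

Only the entry and element levels are modeled. An element holds exactly one
data value from a closed set of six variants: `CODED_TEXT` (code, coding
scheme, optional display), `SIMPLE_TEXT`, `DATE_TIME` (ISO-8601,
timezone-aware), `QUANTITY` (decimal magnitude + non-empty units),
`IDENTIFIER` (value + optional assigning scope), `BOOLEAN`. The closed set
keeps validation decidable; adding a variant is a code change by design.
Higher-level containers (folder/composition/section/cluster) are out of
scope: every packaged archetype is an entry.

### Archetype library

Twelve entry-level concepts ship as YAML fixtures: diagnosis, episodes,
limitation of life-sustaining treatment, administered medication, cumulative
drug dose, prescribed medication, movements between units, clinical
observations, laboratory observations, patients, health problems, and
procedures. The diagnosis entry has the six documented elements
(`episode_id`, `diagnosis`, `diagnosis_datetime`, `patient_id`,
`diagnosis_id`, `source`); the other eleven element lists are
reconstructions chosen to carry exactly what their OMOP correspondence
needs, and are flagged as reconstructions in the fixture comments. The
health-problems concept is a library member only — its upstream source is
free text processed outside this package, so no tabular pipeline feeds it.

Definitions are authored in a documented YAML dialect rather than ADL;
parsing is strict (unknown fields rejected, duplicate node ids rejected,
terminology bindings only on coded elements, archetype ids must match
`<origin>.<concept>.v<n>`). `serialize ∘ parse` is the identity on canonical
form and element order is preserved as authored.

## Terminology binding

Mapping tables (CSV: `local_code, local_system, target_code, target_system,
display`) bind local codes to ICD-10-CM, LOINC or SNOMED CT one-to-one; a
local code with two targets is a table validation error because binding must
be deterministic. Matching is case-sensitive (ICD-10-CM and LOINC codes are
case-significant). Binding is **total**: an unmapped code is preserved as a
`local`-system coded value and the miss is recorded in an unmapped-codes
report, so the mapped set plus the report partitions the input exactly and
no record is dropped during normalization. How unmappable codes should be
handled in a production repository is a policy question; preserve-and-report
is this package's choice, made for auditability. Categorization (e.g.
hospital unit → level of care) is a dimension-keyed lookup with an explicit
`uncategorized` sentinel for misses.

The packaged toy terminology (~100 concepts: 50 ICD-10-CM, 30 LOINC, 20
SNOMED CT, including `H40.9` *unspecified glaucoma*) exists so the worked
example and tests run offline; it is not a clinical vocabulary. No
OHDSI/Athena vocabulary resolution is attempted anywhere: exported
`*_concept_id` columns carry 0 (the CDM convention for "no matching
concept") and the bound codes travel in `*_source_value` columns.

## Extract building

A mapping spec binds each archetype element to a source column with an
optional transform (`bind_code`, `categorize`, `datetime_parse`, or
identity; quantity elements name a second units column). The spec is
validated against both the archetype and the source schema before any row is
processed. Per row, mandatory-element failures (missing value, unparseable
magnitude, bad boolean) quarantine the whole row with a reason naming the
element; `rows seen = entries built + quarantined` is asserted structurally.

Naive source timestamps are localized to a configured timezone
(Europe/Madrid by default, matching the emulated setting); ambiguous
DST wall times take the DST side and nonexistent ones shift forward, so
localization is deterministic. Extracts are packaged per (patient,
archetype), carry fixed provenance (source name + configured extraction
timestamp) so rebuilds are byte-identical, and serialize to a namespaced XML
dialect (`urn:ehrbridge:extract:1`, XSD in `src/ehrbridge/data/extract.xsd`).
Optional elements without a value are omitted entirely. `parse(serialize(x))
== x` holds for every valid extract.

## The three ontology layers

* **Layer 1 (concepts)** — per archetype: one OWL class per entry, one
  property per element (object property for structured values, datatype
  property otherwise), annotated with its value kind. This layer references
  no standard at all, which is what makes the representation
  standard-agnostic: mapping to a different model means adding a layer, not
  changing layer 1.
* **Layer 2 (reference model)** — each concept class `rdfs:subClassOf
  iso13606:Entry`; each element property annotated (and, for structured
  values, ranged) with its reference-model data-value class.
* **Layer 3 (OMOP)** — the concept class is annotated with its CDM table and
  each property with the column(s) it feeds. Annotation axioms (not
  `owl:equivalentClass`) were chosen because the exporter *reads* the mapping
  — no reasoning is involved — and annotations keep the layers strippable.
  An element may feed several columns (a quantity feeds both `quantity` and
  `dose_unit_source_value`); distinct predicates mark the value, units and
  display parts.

The OMOP ontology is generated from a schema pinned to the CDM v5.4 column
names for the eleven supported tables (the ten clinical tables plus
`Procedure_occurrence`). Layer separation is checkable: layer graphs hold no
instance data, the instance graph holds no class axioms, and Turtle
emit→load preserves triple-set equality per graph.

The correspondence configuration maps: patient → Person, episode →
Visit_occurrence, diagnosis → Condition_occurrence, the three medication
archetypes → Drug_exposure, movements → Visit_detail, clinical and
laboratory observations → Measurement, limitation of life-sustaining
treatment → Observation, procedure → Procedure_occurrence. The originating
archetype of each Drug_exposure row is not written into a CDM column — v5.4
has no drug-type source-value column — but is recoverable from the export
manifest's per-archetype instance counts; `drug_type_concept_id` carries 0
like every concept id.

## Instance store

Instance IRIs are SHA-256 hashes of (archetype id, patient id, canonical
entry content), truncated to 64 bits. Content-addressing makes reload
idempotent (an identical entry maps to the same IRI and identical triples)
and the store reproducible. Structured values become typed nodes carrying
their leaf literals (`iso13606:codeValue`, `iso13606:codingScheme`,
`iso13606:magnitude` as `xsd:decimal`, …); scalar values become typed
literals (`xsd:dateTime`, `xsd:boolean`, string). A batch stages all triples
first and commits only if every extract validates and every archetype has a
concept ontology — otherwise nothing is inserted, which keeps the
conservation ledger exact. Two physically identical entries (same patient,
same archetype, same values) are one instance by construction; the synthetic
generator's unique record identifiers make this collapse impossible in
generated data.

## Export

Per table, the generated SPARQL query projects one variable named after each
schema column; archetype blocks are combined with `UNION` when several
concepts feed a table; unmapped columns remain unbound and become empty
cells; structured values are navigated through their reference-model leaf
properties in the query text itself. Transformations that do not fit the
query run in a deterministic tabular post-pass:

* `*_concept_id` → 0; `*_date` derived from the matching `*_datetime`;
  `year/month/day_of_birth` from `birth_datetime`.
* **Derived tables** (no archetype feeds them; the rules are this package's
  decisions): `Observation_period` — per person, the `[min, max]` span of
  all event dates; `Death` — one row per person from episodes whose
  discharge disposition is the configured death code (`DEATH` in the
  synthetic data), latest such episode winning; `Device_exposure` —
  procedure rows whose boolean device flag is set, reshaped into the device
  schema. The flag travels through the query in the `modifier_source_value`
  column as a carrier and is cleared afterwards.
* `Procedure_occurrence` itself is off by default (the default export is
  exactly the ten clinical tables) and available behind
  `ExportConfig(include_procedure_occurrence=True)`; when off, non-device
  procedure rows are counted as logged exclusions so that per-archetype
  conservation (instances = rows + exclusions) still closes.
* **Pseudonymization**: every identifier column is replaced by
  `HMAC-SHA256(salt, id)` truncated to 63 bits (decimal digits, so CDM
  integer typing is honored); `person_source_value` carries a hex form of
  the same transform. The transform is deterministic within a salt, one-way,
  and collision-free at any realistic cohort size (~5·10⁻¹² collision
  probability at 10⁴ ids). Raw identifiers never reach a CSV.
* Rows are sorted by their full post-pass content, so re-export from the
  same store and salt is byte-identical. CSV is RFC 4180 (UTF-8, CRLF,
  header row, ISO-8601 dates).

The integrity report lists foreign-key orphans (person references in the
nine dependent tables, visit references in `Visit_detail`); on synthetic
data it is empty because the generator is referentially consistent.

## Synthetic source data

The generator emulates an emergency-room/hospitalization cohort over the
2020-02-17 … 2022-02-15 inclusion window. Defaults: 40 patients; episodes
per patient Poisson(1.8) (min 1); per episode — diagnoses Poisson(2.5),
prescriptions Poisson(3), administrations Poisson(5), movements Poisson(1.5)
(min 1), clinical observations Poisson(6), laboratory observations
Poisson(8), procedures Poisson(0.8); death probability 0.08 (applied to a
patient's last episode); limitation-of-life-sustaining-treatment probability
0.08 per episode; device-flag probability 0.25 per procedure. The 40-patient
default is a desk-scale profile: every archetype pipeline is exercised with
hundreds to thousands of entries while a full run stays in seconds. Event
times are uniform within the episode span and cumulative doses are the
per-episode, per-drug sums of administrations. Two legacy diagnosis codes
(`DX900`, `DX901`) are deliberately absent from the mapping table to
exercise the preserve-and-report path end to end. The first patient's first
episode always includes the local glaucoma code `DX011` so the worked
example is reproducible at any seed. Same seed → byte-identical files, and
the manifest records exact per-entity counts.

What the generator does **not** emulate: comorbidity structure, plausible
dosing, unit-specific observation ranges, free text, or missing-data
patterns of real hospital systems. Green tests therefore demonstrate the
transformation contract (conservation, typing, round trips, integrity,
anonymization), not clinical robustness against real-world data quality.

## Numerical and encoding choices

Quantities are `decimal.Decimal` end to end (CSV cells show the source's
textual precision; no float round-tripping). Timestamps keep their UTC
offset through extract, store and export; `*_date` columns are the first ten
characters of the local ISO timestamp. Booleans serialize as `true`/`false`.
Coded displays are optional everywhere and never used as match keys.

## Known limitations

* No ADL parsing; archetype specialization/slots and multi-language term
  sets are unsupported.
* No standard-concept (vocabulary) resolution: the export is a
  source-value-level CDM, suitable as input to a downstream vocabulary
  mapping step, not directly for concept-id-based analytics.
* rdflib's in-memory store bounds practical cohort size; the design targets
  correctness and determinism, not triple-store scale.
* The extract XML dialect is a documented subset, not the norm's full
  extract schema; it is sufficient for entry-level content.
* Death/observation-period/device derivation rules are package decisions;
  a deployment with real sources would revisit them against local coding
  practice.
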