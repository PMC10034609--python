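# ehrbridge

**From local hospital tables to EN/ISO 13606 EHR extracts, a three-layer RDF
ontology, and OMOP CDM research tables.**

Health-care institutions record patient data in local, idiosyncratic schemas,
while observational research needs a common relational model (OMOP CDM).
Converting one into the other directly loses granularity and meaning.
`ehrbridge` implements a dual-model route for engineers and medical
informaticians building research repositories:

1. **Archetypes** (EN/ISO 13606 entry level) formalize each clinical concept —
   diagnosis, episode, medication, observations, movements between units,
   limitation of life-sustaining treatment, procedures, patients, health
   problems — as an entry with typed elements.
2. **Extract building** maps source tables onto archetypes, binds local codes
   to standard nomenclatures (ICD-10-CM, LOINC, SNOMED CT), categorizes
   concepts (e.g. hospital units by level of care), and emits validated
   extract XML. Rows that cannot populate a mandatory element are quarantined,
   never dropped: `rows = entries + quarantined` holds exactly.
3. **Three ontology layers** represent the concepts as RDF: concept classes
   and element properties (standard-agnostic), a mapping onto an EN/ISO 13606
   reference-model ontology (`subClassOf iso13606:Entry`, element properties
   typed with reference-model data values), and a mapping onto an OMOP CDM
   ontology (class → table, property → column, e.g. the diagnosis property →
   `condition_source_value`).
4. **Instance loading** inserts each extract entry as a typed instance with
   deterministic IRIs (idempotent reload adds no triples).
5. **Export** generates one SPARQL query per CDM table from the mapping layer
   — one projected variable per column, unmapped columns left unbound — and a
   tabular post-pass derives dates, fills `concept_id` columns with 0,
   computes the derived tables (`Observation_period`, `Death`,
   `Device_exposure`) and pseudonymizes all identifiers with a keyed one-way
   transform. The result is the ten standardized clinical tables
   (`Condition_occurrence`, `Death`, `Device_exposure`, `Drug_exposure`,
   `Measurement`, `Observation`, `Observation_period`, `Person`,
   `Visit_detail`, `Visit_occurrence`) as RFC 4180 CSV, with a referential-
   integrity report and a count manifest.

A deterministic synthetic hospital dataset (`ehrbridge.synthetic`) makes the
whole chain runnable and testable offline; no real patient data is involved.

## Worked example

```python
from ehrbridge.synthetic import generate, GeneratorConfig
from ehrbridge.pipeline import run_pipeline

source = generate(GeneratorConfig(seed=1))          # 40-patient synthetic cohort
result = run_pipeline(source, "work", pseudonym_salt="demo-salt")
print(result.export.manifest["tables"])
```

prints

```
{'Condition_occurrence': 249, 'Death': 3, 'Device_exposure': 14,
 'Drug_exposure': 1096, 'Measurement': 1309, 'Observation': 7,
 'Observation_period': 40, 'Person': 40, 'Visit_detail': 163,
 'Visit_occurrence': 90}
```

— ten tables, with the record-conservation identities visible in the counts:
`Drug_exposure` 1096 = 455 administrations + 264 prescriptions + 377
cumulative doses; `Measurement` 1309 = 524 clinical + 785 laboratory
observations; 61 procedures split into 14 device exposures and 47 logged
exclusions (`Procedure_occurrence` is off by default and available behind
`ExportConfig(include_procedure_occurrence=True)`).

The generator always includes one diagnosis with the local code `DX011`; the
terminology table binds it to ICD-10-CM `H40.9` (unspecified glaucoma), and it
survives into `Condition_occurrence`:

```
{'condition_occurrence_id': '3986593605113175936',
 'person_id': '1426271440995782235',
 'condition_start_date': '2021-12-24',
 'condition_source_value': 'H40.9',
 'visit_occurrence_id': '6918801117344259345'}
```

All identifiers are pseudonyms; no source patient or episode identifier
appears in any exported CSV. `work/extracts/` holds the extract XML per
archetype, `work/ontology/` the Turtle files per layer, `work/omop/` the CSVs,
`integrity_report.csv` and `export_manifest.json`.

The same chain is available from the shell:

```bash
ehrbridge generate --seed 1 --out work/source
ehrbridge pipeline --source work/source --work work --salt-file salt.txt
```

## Documentation

`docs/methods.md` describes the model, the mapping conventions, the
derivation rules for the tables no archetype feeds directly, the synthetic
generator's assumptions, and known limitations.
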