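"""Shared fixtures: packaged configuration and one full pipeline run."""

from __future__ import annotations

import random
import string
from decimal import Decimal

import pytest

from ehrbridge.archetypes import builtin_library
from ehrbridge.extracts import EHRExtract, Entry, Provenance
from ehrbridge.pipeline import builtin_categories, builtin_terminology, run_pipeline
from ehrbridge.rm import DataValue, ValueKind
from ehrbridge.synthetic import GeneratorConfig, generate

SALT = "unit-test-salt"


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture()
def terminology_table():
    # function-scoped: the unmapped report is mutable
    return builtin_terminology()


@pytest.fixture()
def category_rules():
    return builtin_categories()


@pytest.fixture(scope="session")
def default_source():
    """The synthetic fixture at its default configuration."""
    return generate(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def pipeline(default_source, tmp_path_factory):
    """One full end-to-end run shared by the export and acceptance tests."""
    work = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(default_source, work, pseudonym_salt=SALT)


@pytest.fixture(scope="session")
def small_source():
    return generate(GeneratorConfig(seed=7, n_patients=6))


def _random_value(rng: random.Random, kind: ValueKind) -> DataValue:
    def word(n=8):
        return "".join(rng.choices(string.ascii_letters + string.digits, k=n))

    if kind is ValueKind.CODED_TEXT:
        return DataValue.coded_text(
            word(6), rng.choice(["ICD-10-CM", "LOINC", "SNOMED CT", "local"]),
            word(12) if rng.random() < 0.5 else None,
        )
    if kind is ValueKind.SIMPLE_TEXT:
        return DataValue.simple_text(word(rng.randint(1, 20)))
    if kind is ValueKind.DATE_TIME:
        return DataValue.date_time(
            f"20{rng.randint(10, 29)}-{rng.randint(1, 12):02d}-"
            f"{rng.randint(1, 28):02d}T{rng.randint(0, 23):02d}:"
            f"{rng.randint(0, 59):02d}:{rng.randint(0, 59):02d}+01:00"
        )
    if kind is ValueKind.QUANTITY:
        return DataValue.quantity(Decimal(rng.randint(0, 10**6)) / 100, word(3))
    if kind is ValueKind.IDENTIFIER:
        return DataValue.identifier(word(10), word(4) if rng.random() < 0.5 else None)
    return DataValue.boolean(rng.random() < 0.5)


def random_extract(rng: random.Random, library) -> EHRExtract:
    """A random valid extract over random archetypes of the library."""
    patient = "P" + "".join(rng.choices(string.digits, k=6))
    entries = []
    for _ in range(rng.randint(1, 4)):
        archetype = rng.choice(list(library))
        values = {}
        for el in archetype.entry.elements:
            if el.mandatory or rng.random() < 0.5:
                values[el.node_id] = _random_value(rng, el.kind)
        entries.append(Entry(archetype_id=archetype.archetype_id, values=values))
    return EHRExtract(
        extract_id=f"x-{patient}",
        patient_id=patient,
        provenance=Provenance(source="HIS", extracted_at="2022-02-15T00:00:00+01:00"),
        entries=entries,
    )
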