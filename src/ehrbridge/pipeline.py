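"""End-to-end orchestration: source tables → extracts → ontology → OMOP CSV.

Thin glue over the stage modules, using the packaged archetype library,
terminology tables and mapping configurations. Each stage's accounting is
kept so that record conservation can be audited across the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

from ehrbridge.archetypes import ArchetypeLibrary, builtin_library
from ehrbridge.export import ExportConfig, ExportResult, export_all
from ehrbridge.extracts import (
    BuildReport,
    EHRExtract,
    ExtractConfig,
    MappingSpec,
    build_extracts,
    serialize_extract,
)
from ehrbridge.instances import InstanceBatch, load_extracts
from ehrbridge.ontology import TripleGraph, load_omop_mapping
from ehrbridge.synthetic import SourceDataset
from ehrbridge.terminology import CategoryRules, MappingTable


def _data_path(rel: str) -> Path:
    return Path(str(resources.files("ehrbridge").joinpath("data"))) / rel


def builtin_terminology() -> MappingTable:
    return MappingTable.from_csv(_data_path("terminology/concept_mappings.csv"))


def builtin_categories() -> CategoryRules:
    return CategoryRules.from_csv(_data_path("terminology/categories.csv"))


def builtin_extract_mappings() -> List[MappingSpec]:
    d = _data_path("mappings/extract")
    return [MappingSpec.from_yaml(p.read_text(encoding="utf-8")) for p in sorted(d.glob("*.yaml"))]


@dataclass
class PipelineResult:
    extracts: Dict[str, List[EHRExtract]] = field(default_factory=dict)
    build_reports: Dict[str, BuildReport] = field(default_factory=dict)
    store: Optional[TripleGraph] = None
    batch: Optional[InstanceBatch] = None
    export: Optional[ExportResult] = None
    extract_dir: Optional[Path] = None
    export_dir: Optional[Path] = None

    @property
    def entries_built(self) -> Dict[str, int]:
        return {aid: r.entries_built for aid, r in self.build_reports.items()}


def run_pipeline(
    source: SourceDataset,
    work_dir: Path | str,
    pseudonym_salt: str,
    library: Optional[ArchetypeLibrary] = None,
    extract_config: Optional[ExtractConfig] = None,
    export_config: Optional[ExportConfig] = None,
) -> PipelineResult:
    """Run the complete chain and write extracts, Turtle layers and CSVs."""
    work = Path(work_dir)
    library = library if library is not None else builtin_library()
    terminology = builtin_terminology()
    categories = builtin_categories()
    extract_config = extract_config or ExtractConfig()

    result = PipelineResult()
    result.extract_dir = work / "extracts"
    all_extracts: List[EHRExtract] = []
    for mapping in builtin_extract_mappings():
        archetype = library.get(mapping.archetype_id)
        extracts, report = build_extracts(
            source, mapping, archetype, terminology, categories, extract_config
        )
        result.extracts[mapping.archetype_id] = extracts
        result.build_reports[mapping.archetype_id] = report
        out = result.extract_dir / archetype.concept
        out.mkdir(parents=True, exist_ok=True)
        for extract in extracts:
            (out / f"{extract.extract_id}.xml").write_bytes(
                serialize_extract(extract, library)
            )
        quarantine = report.quarantine_frame()
        if len(quarantine):
            quarantine.to_csv(out / "quarantine.csv", index=False)
        all_extracts.extend(extracts)

    store = TripleGraph()
    store.build_layers(library, load_omop_mapping())
    result.store = store
    result.batch = load_extracts(all_extracts, store, library)
    store.save_turtle_layers(work / "ontology")

    result.export_dir = work / "omop"
    result.export = export_all(
        store,
        pseudonym_salt=pseudonym_salt,
        out_dir=result.export_dir,
        config=export_config,
    )
    return result
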