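"""Terminology binding and concept categorization.

Normalization maps local hospital codes to standard nomenclatures
(ICD-10-CM, LOINC, SNOMED CT), attaches readable descriptions, and groups
certain concepts along configured dimensions (e.g. hospital units by level
of care). Binding is total: a code with no mapping is preserved in the
``local`` system and recorded in an unmapped-codes report, so no record is
ever dropped at this stage. Matching is case-sensitive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from ehrbridge.rm import DataValue

TARGET_SYSTEMS = ("ICD-10-CM", "LOINC", "SNOMED CT", "local")

UNCATEGORIZED = "uncategorized"


class TerminologyError(ValueError):
    """A mapping/category table or lookup input is invalid."""


class ConceptMapping(BaseModel):
    """One row of a mapping table: a local code bound to a standard code."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    local_code: str = Field(min_length=1)
    local_system: str = Field(min_length=1)
    target_code: str = Field(min_length=1)
    target_system: Literal["ICD-10-CM", "LOINC", "SNOMED CT", "local"]
    display: str = ""


class CategoryRule(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    source_value: str = Field(min_length=1)
    dimension: str = Field(min_length=1)
    category: str = Field(min_length=1)


@dataclass
class UnmappedReport:
    """Multiset of (local_code, local_system) lookups that found no mapping."""

    misses: Counter = field(default_factory=Counter)

    def record(self, local_code: str, local_system: str) -> None:
        self.misses[(local_code, local_system)] += 1

    @property
    def distinct_codes(self) -> set:
        return set(self.misses)

    @property
    def total(self) -> int:
        return sum(self.misses.values())


class MappingTable:
    """A validated one-to-one local→standard code mapping table."""

    def __init__(self, mappings: List[ConceptMapping]):
        index: Dict[Tuple[str, str], ConceptMapping] = {}
        for m in mappings:
            key = (m.local_code, m.local_system)
            if key in index:
                raise TerminologyError(
                    f"duplicate mapping for local code {m.local_code!r} "
                    f"in system {m.local_system!r}"
                )
            index[key] = m
        self._index = index
        self.unmapped = UnmappedReport()

    def __len__(self) -> int:
        return len(self._index)

    @classmethod
    def from_csv(cls, path: Path | str) -> "MappingTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        expected = ["local_code", "local_system", "target_code", "target_system", "display"]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise TerminologyError(f"mapping CSV {path} lacks columns {missing}")
        return cls([ConceptMapping(**row) for row in df[expected].to_dict("records")])

    def bind(
        self, local_code: str, local_system: str, display: Optional[str] = None
    ) -> DataValue:
        """Bind one local code; see :func:`bind_code`."""
        if not local_code:
            raise TerminologyError("empty local_code")
        if local_system in TARGET_SYSTEMS and local_system != "local":
            # already expressed in a target nomenclature: identity binding
            return DataValue.coded_text(local_code, local_system, display)
        m = self._index.get((local_code, local_system))
        if m is None:
            self.unmapped.record(local_code, local_system)
            return DataValue.coded_text(local_code, "local", display)
        return DataValue.coded_text(m.target_code, m.target_system, m.display or None)


def bind_code(local_code: str, local_system: str, table: MappingTable) -> DataValue:
    """Map a local code to a standard CODED_TEXT value.

    Returns the bound standard code with its readable description; a code
    absent from the table comes back unchanged in system ``local`` and the
    miss is added to ``table.unmapped``. A code whose system already is a
    standard nomenclature passes through unchanged.
    """
    return table.bind(local_code, local_system)


class CategoryRules:
    """Concept-categorization rules grouped by dimension."""

    def __init__(self, rules: List[CategoryRule]):
        self._by_dim: Dict[str, Dict[str, str]] = {}
        for r in rules:
            dim = self._by_dim.setdefault(r.dimension, {})
            if r.source_value in dim:
                raise TerminologyError(
                    f"duplicate category rule for {r.source_value!r} "
                    f"in dimension {r.dimension!r}"
                )
            dim[r.source_value] = r.category
        self.unmatched = UnmappedReport()

    @classmethod
    def from_csv(cls, path: Path | str) -> "CategoryRules":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        expected = ["source_value", "dimension", "category"]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise TerminologyError(f"category CSV {path} lacks columns {missing}")
        return cls([CategoryRule(**row) for row in df[expected].to_dict("records")])

    @property
    def dimensions(self) -> set:
        return set(self._by_dim)

    def categorize(self, source_value: str, dimension: str) -> str:
        if dimension not in self._by_dim:
            raise TerminologyError(f"unknown categorization dimension {dimension!r}")
        cat = self._by_dim[dimension].get(source_value)
        if cat is None:
            self.unmatched.record(source_value, dimension)
            return UNCATEGORIZED
        return cat


def categorize(source_value: str, dimension: str, rules: CategoryRules) -> str:
    """Group a source value along a dimension; misses yield ``uncategorized``."""
    return rules.categorize(source_value, dimension)
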