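"""EN/ISO 13606 reference-model subset: the single data value of an element.

Only the entry and element levels of the reference model are represented
(no folder/composition/section/cluster), and the data-value variants are a
closed set of six covering every element in the packaged archetype library:
coded text, simple text, date-time, physical quantity, identifier, boolean.
"""

from __future__ import annotations

import enum
from decimal import Decimal
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator


class ValueKind(str, enum.Enum):
    """The six supported reference-model data-value variants."""

    CODED_TEXT = "CODED_TEXT"
    SIMPLE_TEXT = "SIMPLE_TEXT"
    DATE_TIME = "DATE_TIME"
    QUANTITY = "QUANTITY"
    IDENTIFIER = "IDENTIFIER"
    BOOLEAN = "BOOLEAN"


#: Which fields each variant populates (everything else must be None).
_VARIANT_FIELDS = {
    ValueKind.CODED_TEXT: {"code", "code_system", "display"},
    ValueKind.SIMPLE_TEXT: {"text"},
    ValueKind.DATE_TIME: {"timestamp"},
    ValueKind.QUANTITY: {"magnitude", "units"},
    ValueKind.IDENTIFIER: {"id_value", "scope"},
    ValueKind.BOOLEAN: {"flag"},
}

#: Optional fields within a variant (may legitimately be None).
_VARIANT_OPTIONAL = {
    ValueKind.CODED_TEXT: {"display"},
    ValueKind.IDENTIFIER: {"scope"},
}


class DataValue(BaseModel):
    """A tagged-union element value; exactly one variant is populated.

    Invariants enforced at construction: the fields of the tagged variant
    (and only those) are set; CODED_TEXT always carries a non-empty
    ``code_system``; QUANTITY always carries non-empty ``units``.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    kind: ValueKind
    # CODED_TEXT
    code: Optional[str] = None
    code_system: Optional[str] = None
    display: Optional[str] = None
    # SIMPLE_TEXT
    text: Optional[str] = None
    # DATE_TIME (ISO-8601 string, timezone-aware in built extracts)
    timestamp: Optional[str] = None
    # QUANTITY
    magnitude: Optional[Decimal] = None
    units: Optional[str] = None
    # IDENTIFIER
    id_value: Optional[str] = None
    scope: Optional[str] = None
    # BOOLEAN
    flag: Optional[bool] = None

    @model_validator(mode="after")
    def _one_variant(self) -> "DataValue":
        allowed = _VARIANT_FIELDS[self.kind]
        optional = _VARIANT_OPTIONAL.get(self.kind, set())
        for field in _VARIANT_FIELDS[ValueKind.CODED_TEXT].union(
            *_VARIANT_FIELDS.values()
        ):
            value = getattr(self, field)
            if field in allowed:
                if field not in optional and value is None:
                    raise ValueError(f"{self.kind.value} requires field {field!r}")
            elif value is not None:
                raise ValueError(
                    f"{self.kind.value} must not populate field {field!r}"
                )
        if self.kind is ValueKind.CODED_TEXT and not self.code_system:
            raise ValueError("CODED_TEXT requires a non-empty code_system")
        if self.kind is ValueKind.QUANTITY and not self.units:
            raise ValueError("QUANTITY requires a non-empty units string")
        return self

    # -- convenience constructors -------------------------------------------

    @classmethod
    def coded_text(
        cls, code: str, code_system: str, display: Optional[str] = None
    ) -> "DataValue":
        return cls(
            kind=ValueKind.CODED_TEXT, code=code, code_system=code_system, display=display
        )

    @classmethod
    def simple_text(cls, text: str) -> "DataValue":
        return cls(kind=ValueKind.SIMPLE_TEXT, text=text)

    @classmethod
    def date_time(cls, timestamp: str) -> "DataValue":
        return cls(kind=ValueKind.DATE_TIME, timestamp=timestamp)

    @classmethod
    def quantity(cls, magnitude: Decimal | float | str, units: str) -> "DataValue":
        return cls(kind=ValueKind.QUANTITY, magnitude=Decimal(str(magnitude)), units=units)

    @classmethod
    def identifier(cls, id_value: str, scope: Optional[str] = None) -> "DataValue":
        return cls(kind=ValueKind.IDENTIFIER, id_value=id_value, scope=scope)

    @classmethod
    def boolean(cls, flag: bool) -> "DataValue":
        return cls(kind=ValueKind.BOOLEAN, flag=flag)
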