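"""Domain model for the nested survey-schema graph (protocol > activity > item).

A *protocol* orders one or more *activities* (questionnaires); each activity
orders *items* (questions) and may define *compute rules* (derived scores such
as a subscale mean). Items carry *response options* — the allowed value space:
an ordered choice list, numeric bounds, and designated missing codes.

Every node carries a :class:`VersionedId` pinning it to an immutable version
(a content digest or a semantic tag), so responses can always be traced to the
exact schema documents in force when they were collected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Optional

VERSION_MARKER = "/v/"
UNPINNED = "unpinned"

INPUT_TYPES = frozenset(
    {
        "radio",
        "select",
        "multiselect",
        "slider",
        "integer",
        "decimal",
        "text",
        "textarea",
        "date",
        "audio_record",
        "video_record",
        "file_upload",
        "static_display",
    }
)

NUMERIC_INPUT_TYPES = frozenset({"integer", "decimal", "slider"})

VALUE_TYPES = frozenset({"integer", "decimal", "string", "code"})

VARNAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

# Syntactic check only (language-subtag well-formedness, not registry validity).
BCP47_RE = re.compile(r"^[A-Za-z]{2,8}(-[A-Za-z0-9]{1,8})*$")


class ModelError(ValueError):
    """Raised when a graph object violates a structural invariant at build time."""


@dataclass
class VersionedId:
    """Version-pinned identifier: ``<base>/v/<version>/<path>``.

    ``version`` is either a content digest (``sha256-<hex>``) or a semantic
    tag; the digest functions as an immutable pin, standing in for a commit
    reference on a hosting service.
    """

    base: str
    version: str = UNPINNED
    path: str = ""

    def iri(self) -> str:
        return f"{self.base}{VERSION_MARKER}{self.version}/{self.path}"

    @classmethod
    def parse(cls, iri: str) -> "VersionedId":
        base, marker, rest = iri.partition(VERSION_MARKER)
        if not marker or "/" not in rest:
            raise ModelError(f"not a versioned IRI: {iri!r}")
        version, _, path = rest.partition("/")
        return cls(base=base, version=version, path=path)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.iri()


@dataclass
class LanguageMap:
    """Per-language text, keyed by BCP-47 code, with default-language fallback."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ModelError("LanguageMap requires at least one entry")
        for code in self.entries:
            if not BCP47_RE.match(code):
                raise ModelError(f"invalid language code: {code!r}")

    def get(self, lang: str, default_lang: str = "en") -> str:
        if lang in self.entries:
            return self.entries[lang]
        if default_lang in self.entries:
            return self.entries[default_lang]
        return next(iter(self.entries.values()))

    @classmethod
    def of(cls, text: str, lang: str = "en") -> "LanguageMap":
        return cls({lang: text})


@dataclass
class Choice:
    value: Any
    label: LanguageMap


@dataclass
class ResponseOptions:
    """Allowed value space of an item.

    ``missing_codes`` are values meaning declined/skipped; they always pass
    validation and evaluate as missing inside expressions.
    """

    value_type: str = "string"
    choices: list[Choice] = field(default_factory=list)
    min_value: Optional[float] = None
    max_value: Optional[float] = None
    multiple_choice: bool = False
    missing_codes: list[Any] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.value_type not in VALUE_TYPES:
            raise ModelError(f"unknown value_type: {self.value_type!r}")
        values = [c.value for c in self.choices]
        if len(values) != len(set(map(repr, values))):
            raise ModelError("choice values must be unique")

    def choice_values(self) -> list[Any]:
        return [c.value for c in self.choices]


@dataclass
class Item:
    """One question or display element."""

    name: str  # document name, usually equal to its variable name
    question: LanguageMap
    input_type: str
    response_options: Optional[ResponseOptions] = None
    extras: dict[str, Any] = field(default_factory=dict)
    id: VersionedId = field(default_factory=lambda: VersionedId(base=""))

    def __post_init__(self) -> None:
        if self.input_type not in INPUT_TYPES:
            raise ModelError(f"unknown input_type: {self.input_type!r}")


@dataclass
class ItemRef:
    """An activity's ordered reference to an item, with its variable binding."""

    variable_name: str
    item: Item
    visibility: Optional[str] = None  # expression source, None = always visible
    required: bool = False

    def __post_init__(self) -> None:
        if not VARNAME_RE.match(self.variable_name):
            raise ModelError(f"invalid variable name: {self.variable_name!r}")


@dataclass
class ComputeRule:
    """A derived variable: ``target <- expression`` over item variables."""

    target: str
    expression: str

    def __post_init__(self) -> None:
        if not VARNAME_RE.match(self.target):
            raise ModelError(f"invalid compute target: {self.target!r}")


@dataclass
class Activity:
    name: str
    pref_label: LanguageMap
    item_order: list[ItemRef] = field(default_factory=list)
    compute_rules: list[ComputeRule] = field(default_factory=list)
    id: VersionedId = field(default_factory=lambda: VersionedId(base=""))

    def variable_names(self) -> list[str]:
        return [ref.variable_name for ref in self.item_order]

    def get_item_ref(self, variable_name: str) -> Optional[ItemRef]:
        for ref in self.item_order:
            if ref.variable_name == variable_name:
                return ref
        return None


@dataclass
class ActivityRef:
    name: str
    activity: Activity
    visibility: Optional[str] = None
    required: bool = False


@dataclass
class Protocol:
    """Top-level study definition ordering one or more activities."""

    name: LanguageMap
    description: LanguageMap
    activity_order: list[ActivityRef] = field(default_factory=list)
    schema_version: str = "1.0.0"
    license: str = "CC-BY-4.0"
    default_language: str = "en"
    base_iri: str = "https://example.org/surveygraph/protocol"
    id: VersionedId = field(default_factory=lambda: VersionedId(base=""))

    def activities(self) -> list[Activity]:
        return [ref.activity for ref in self.activity_order]

    def get_activity(self, name: str) -> Optional[Activity]:
        for ref in self.activity_order:
            if ref.name == name:
                return ref.activity
        return None

    def find_item(self, variable_name: str) -> Optional[tuple[Activity, ItemRef]]:
        for act in self.activities():
            ref = act.get_item_ref(variable_name)
            if ref is not None:
                return act, ref
        return None

    def node_count(self) -> int:
        """Protocol + activities + items."""
        return 1 + len(self.activity_order) + sum(
            len(a.item_order) for a in self.activities()
        )


@dataclass
class ResponseRecord:
    """One answered item, with provenance links to version-pinned schema ids."""

    respondent: str
    protocol_id: VersionedId
    activity_id: VersionedId
    item_id: VersionedId
    variable_name: str
    value: Any
    answered_at: str  # ISO-8601
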