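"""Load/save the schema graph as a tree of canonical JSON-LD documents.

Layout::

    <root>/protocol.jsonld
    <root>/activities/<name>/activity.jsonld
    <root>/activities/<name>/items/<var>.jsonld

Responses: ``<out>/<respondent>/<activity>.jsonld``.

Version pinning is Merkle-style: item digests are computed first, the
activity document embeds the pinned item IRIs and is digested in turn, and
the protocol document pins the activity IRIs — so the protocol digest
transitively identifies the exact content of the whole tree, the local
equivalent of a commit pin.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any, Optional

from .canonical import canonical_dumps, content_digest, read_json, write_canonical
from .model import (
    Activity,
    ActivityRef,
    Choice,
    Item,
    ItemRef,
    ComputeRule,
    LanguageMap,
    ModelError,
    Protocol,
    ResponseOptions,
    ResponseRecord,
    VersionedId,
)


class ResolutionError(ValueError):
    """A reference inside the tree points at a missing document."""


class ParseError(ValueError):
    """A document is not valid JSON or lacks required keys; carries its path."""


class ProvenanceError(ValueError):
    """A response record references a schema node absent from the graph."""


def _context_document() -> dict:
    ref = importlib.resources.files("surveygraph").joinpath("data/context.jsonld")
    import json

    return json.loads(ref.read_text(encoding="utf-8"))


_CTX_DOC = _context_document()
CONTEXT_DIGEST = content_digest(_CTX_DOC)
CONTEXT_IRI = f"https://example.org/surveygraph/context/v/{CONTEXT_DIGEST}/context.jsonld"


# ---------------------------------------------------------------------------
# Document building (model -> dict)
# ---------------------------------------------------------------------------

def _lm(lm: LanguageMap) -> dict:
    return dict(sorted(lm.entries.items()))


def _options_doc(opts: ResponseOptions) -> dict:
    doc: dict[str, Any] = {
        "valueType": opts.value_type,
        "multipleChoice": opts.multiple_choice,
    }
    if opts.choices:
        doc["choices"] = [{"value": c.value, "label": _lm(c.label)} for c in opts.choices]
    if opts.min_value is not None:
        doc["minValue"] = opts.min_value
    if opts.max_value is not None:
        doc["maxValue"] = opts.max_value
    if opts.missing_codes:
        doc["missingCodes"] = list(opts.missing_codes)
    return doc


def item_document(item: Item) -> dict:
    doc: dict[str, Any] = {
        "@context": CONTEXT_IRI,
        "@type": "Item",
        "question": _lm(item.question),
        "inputType": item.input_type,
    }
    if item.response_options is not None:
        doc["responseOptions"] = _options_doc(item.response_options)
    if item.extras:
        doc["extras"] = dict(sorted(item.extras.items()))
    return doc


def activity_document(activity: Activity, item_iris: dict[str, str]) -> dict:
    order = []
    for ref in activity.item_order:
        entry: dict[str, Any] = {
            "ref": item_iris[ref.variable_name],
            "variableName": ref.variable_name,
            "required": ref.required,
        }
        if ref.visibility is not None:
            entry["isVis"] = ref.visibility
        order.append(entry)
    doc: dict[str, Any] = {
        "@context": CONTEXT_IRI,
        "@type": "Activity",
        "prefLabel": _lm(activity.pref_label),
        "itemOrder": order,
    }
    if activity.compute_rules:
        doc["computeRules"] = [
            {"variableName": r.target, "expression": r.expression}
            for r in activity.compute_rules
        ]
    return doc


def protocol_document(protocol: Protocol, activity_iris: dict[str, str]) -> dict:
    order = []
    for ref in protocol.activity_order:
        entry: dict[str, Any] = {
            "ref": activity_iris[ref.name],
            "name": ref.name,
            "required": ref.required,
        }
        if ref.visibility is not None:
            entry["isVis"] = ref.visibility
        order.append(entry)
    return {
        "@context": CONTEXT_IRI,
        "@type": "Protocol",
        "name": _lm(protocol.name),
        "description": _lm(protocol.description),
        "schemaVersion": protocol.schema_version,
        "license": protocol.license,
        "defaultLanguage": protocol.default_language,
        "activityOrder": order,
    }


def pin_versions(protocol: Protocol) -> dict[str, dict]:
    """Assign digest-pinned VersionedIds to every node, bottom-up.

    Returns the documents keyed by relative path, each with its ``@id`` set.
    Mutates the graph's ``id`` fields in place (idempotent).
    """
    base = protocol.base_iri
    docs: dict[str, dict] = {}
    activity_iris: dict[str, str] = {}
    for aref in protocol.activity_order:
        act = aref.activity
        item_iris: dict[str, str] = {}
        for iref in act.item_order:
            path = f"activities/{aref.name}/items/{iref.variable_name}.jsonld"
            doc = item_document(iref.item)
            vid = VersionedId(base=base, version=content_digest(doc), path=path)
            doc["@id"] = vid.iri()
            iref.item.id = vid
            item_iris[iref.variable_name] = vid.iri()
            docs[path] = doc
        path = f"activities/{aref.name}/activity.jsonld"
        doc = activity_document(act, item_iris)
        vid = VersionedId(base=base, version=content_digest(doc), path=path)
        doc["@id"] = vid.iri()
        act.id = vid
        activity_iris[aref.name] = vid.iri()
        docs[path] = doc
    doc = protocol_document(protocol, activity_iris)
    vid = VersionedId(base=base, version=content_digest(doc), path="protocol.jsonld")
    doc["@id"] = vid.iri()
    protocol.id = vid
    docs["protocol.jsonld"] = doc
    return docs


def save_protocol(protocol: Protocol, root_path: str | Path) -> None:
    """Write one canonical document per node; identical graphs yield
    byte-identical trees. Structural invariants are checked before any file
    is written."""
    _check_invariants(protocol)
    docs = pin_versions(protocol)
    root = Path(root_path)
    rendered = {path: canonical_dumps(doc) for path, doc in docs.items()}
    for path, text in rendered.items():
        target = root / path
        target.parent.mkdir(parents=True, exist_ok=True)
        with open(target, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)


def _check_invariants(protocol: Protocol) -> None:
    names = [ref.name for ref in protocol.activity_order]
    if len(names) != len(set(names)):
        raise ModelError("duplicate activity references in protocol")
    for act in protocol.activities():
        variables = act.variable_names()
        if len(variables) != len(set(variables)):
            raise ModelError(f"duplicate variable names in activity {act.name!r}")
        targets = [r.target for r in act.compute_rules]
        if set(targets) & set(variables):
            raise ModelError(f"compute target collides with item variable in {act.name!r}")
        if len(targets) != len(set(targets)):
            raise ModelError(f"duplicate compute targets in {act.name!r}")


# ---------------------------------------------------------------------------
# Loading (dict -> model)
# ---------------------------------------------------------------------------

def _parse_lm(doc: Any, path: str, key: str) -> LanguageMap:
    if not isinstance(doc, dict) or not doc:
        raise ParseError(f"{path}: {key} must be a non-empty language map")
    return LanguageMap(dict(doc))


def _parse_options(doc: dict) -> ResponseOptions:
    choices = [
        Choice(value=c["value"], label=LanguageMap(dict(c["label"])))
        for c in doc.get("choices", [])
    ]
    return ResponseOptions(
        value_type=doc.get("valueType", "string"),
        choices=choices,
        min_value=doc.get("minValue"),
        max_value=doc.get("maxValue"),
        multiple_choice=bool(doc.get("multipleChoice", False)),
        missing_codes=list(doc.get("missingCodes", [])),
    )


def _load_document(path: Path) -> dict:
    if not path.is_file():
        raise ResolutionError(f"missing document: {path}")
    try:
        doc = read_json(path)
    except ValueError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "@type" not in doc:
        raise ParseError(f"{path}: not a typed JSON-LD document")
    return doc


def _doc_id(doc: dict, path: Path) -> VersionedId:
    iri = doc.get("@id")
    if not iri:
        raise ParseError(f"{path}: document has no @id")
    return VersionedId.parse(iri)


def load_protocol(root_path: str | Path) -> Protocol:
    """Load and fully resolve a protocol tree; dangling references raise
    :class:`ResolutionError` naming the missing IRI/path."""
    root = Path(root_path)
    pdoc = _load_document(root / "protocol.jsonld")
    pid = _doc_id(pdoc, root / "protocol.jsonld")

    activity_refs = []
    for entry in pdoc.get("activityOrder", []):
        name = entry["name"]
        apath = root / "activities" / name / "activity.jsonld"
        if not apath.is_file():
            raise ResolutionError(
                f"dangling activity reference {entry.get('ref', name)!r}: missing {apath}"
            )
        adoc = _load_document(apath)
        aid = _doc_id(adoc, apath)

        item_refs = []
        for ientry in adoc.get("itemOrder", []):
            var = ientry["variableName"]
            ipath = root / "activities" / name / "items" / f"{var}.jsonld"
            if not ipath.is_file():
                raise ResolutionError(
                    f"dangling item reference {ientry.get('ref', var)!r}: missing {ipath}"
                )
            idoc = _load_document(ipath)
            options_field = idoc.get("responseOptions")
            if isinstance(options_field, str):
                # reference to a shared options document, relative to the item
                opath = (ipath.parent / options_field).resolve()
                if not opath.is_file():
                    raise ResolutionError(
                        f"dangling responseOptions reference {options_field!r} in {ipath}"
                    )
                options = _parse_options(read_json(opath))
            elif options_field is not None:
                options = _parse_options(options_field)
            else:
                options = None
            item = Item(
                name=var,
                question=_parse_lm(idoc.get("question"), str(ipath), "question"),
                input_type=idoc["inputType"],
                response_options=options,
                extras=dict(idoc.get("extras", {})),
                id=_doc_id(idoc, ipath),
            )
            item_refs.append(
                ItemRef(
                    variable_name=var,
                    item=item,
                    visibility=ientry.get("isVis"),
                    required=bool(ientry.get("required", False)),
                )
            )

        rules = [
            ComputeRule(target=r["variableName"], expression=r["expression"])
            for r in adoc.get("computeRules", [])
        ]
        activity = Activity(
            name=name,
            pref_label=_parse_lm(adoc.get("prefLabel"), str(apath), "prefLabel"),
            item_order=item_refs,
            compute_rules=rules,
            id=aid,
        )
        activity_refs.append(
            ActivityRef(
                name=name,
                activity=activity,
                visibility=entry.get("isVis"),
                required=bool(entry.get("required", False)),
            )
        )

    return Protocol(
        name=_parse_lm(pdoc.get("name"), "protocol.jsonld", "name"),
        description=_parse_lm(pdoc.get("description"), "protocol.jsonld", "description"),
        activity_order=activity_refs,
        schema_version=pdoc.get("schemaVersion", "1.0.0"),
        license=pdoc.get("license", ""),
        default_language=pdoc.get("defaultLanguage", "en"),
        base_iri=pid.base,
        id=pid,
    )


# ---------------------------------------------------------------------------
# Response records
# ---------------------------------------------------------------------------

def write_responses(records: list[ResponseRecord], out_dir: str | Path, protocol: Protocol) -> list[Path]:
    """Write one JSON-LD file per respondent per activity, embedding the
    version-pinned protocol/activity/item IRIs."""
    known_items = {}
    for aref in protocol.activity_order:
        for iref in aref.activity.item_order:
            known_items[iref.item.id.iri()] = (aref.activity.id.iri(), iref.variable_name)

    grouped: dict[tuple[str, str], list[ResponseRecord]] = {}
    for rec in records:
        item_iri = rec.item_id.iri()
        if item_iri not in known_items:
            raise ProvenanceError(f"record references unknown item {item_iri}")
        act_iri, _ = known_items[item_iri]
        if rec.activity_id.iri() != act_iri:
            raise ProvenanceError(
                f"record activity {rec.activity_id.iri()} does not own item {item_iri}"
            )
        if rec.protocol_id.iri() != protocol.id.iri():
            raise ProvenanceError(
                f"record pinned to protocol {rec.protocol_id.iri()}, "
                f"graph is {protocol.id.iri()}"
            )
        act_name = rec.activity_id.path.split("/")[1]
        grouped.setdefault((rec.respondent, act_name), []).append(rec)

    out = Path(out_dir)
    written = []
    for (respondent, act_name), recs in sorted(grouped.items()):
        doc = {
            "@context": CONTEXT_IRI,
            "@type": "ResponseFile",
            "respondent": respondent,
            "protocol": recs[0].protocol_id.iri(),
            "activity": recs[0].activity_id.iri(),
            "responses": [
                {
                    "@type": "Response",
                    "item": r.item_id.iri(),
                    "variableName": r.variable_name,
                    "value": r.value,
                    "answeredAt": r.answered_at,
                }
                for r in recs
            ],
        }
        target = out / respondent / f"{act_name}.jsonld"
        target.parent.mkdir(parents=True, exist_ok=True)
        write_canonical(target, doc)
        written.append(target)
    return written


def read_responses(in_dir: str | Path) -> list[ResponseRecord]:
    """Read back all response files under a directory tree."""
    records = []
    for path in sorted(Path(in_dir).rglob("*.jsonld")):
        doc = _load_document(path)
        if doc.get("@type") != "ResponseFile":
            continue
        pid = VersionedId.parse(doc["protocol"])
        aid = VersionedId.parse(doc["activity"])
        for entry in doc.get("responses", []):
            records.append(
                ResponseRecord(
                    respondent=doc["respondent"],
                    protocol_id=pid,
                    activity_id=aid,
                    item_id=VersionedId.parse(entry["item"]),
                    variable_name=entry["variableName"],
                    value=entry["value"],
                    answered_at=entry["answeredAt"],
                )
            )
    return records
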