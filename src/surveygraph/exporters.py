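"""One-way exports: FHIR R4 Questionnaire, BIDS phenotype tables, and flat
common-data-elements (CDE) submission tables.

The FHIR export describes the *instrument* (so computed variables are not
included); BIDS and CDE exports carry *data*, so computed scores are included
there and flagged as derived in the BIDS sidecar. All exports are read-only
with respect to the graph and records.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
import yaml

from .canonical import write_canonical
from .expr import (
    Binary,
    Call,
    Lit,
    MISSING,
    Node,
    Unary,
    Var,
    compute_scores,
    parse_expression,
)
from .model import Activity, Item, Protocol, ResponseRecord

logger = logging.getLogger(__name__)

UNTRANSLATABLE_VIS_EXT = (
    "https://example.org/surveygraph/vocab#untranslatable-visibility"
)


class ConfigurationError(ValueError):
    """A CDE mapping references variables absent from the graph."""


# ---------------------------------------------------------------------------
# FHIR R4 Questionnaire
# ---------------------------------------------------------------------------

_FHIR_TYPE = {
    "radio": "choice",
    "select": "choice",
    "multiselect": "choice",
    "slider": "integer",
    "integer": "integer",
    "decimal": "decimal",
    "text": "string",
    "textarea": "text",
    "date": "date",
    "audio_record": "attachment",
    "video_record": "attachment",
    "file_upload": "attachment",
    "static_display": "display",
}

_FHIR_OPERATORS = {"==": "=", "!=": "!=", "<": "<", "<=": "<=", ">": ">", ">=": ">="}


def _conjunction_leaves(node: Node) -> Optional[list[Node]]:
    """Flatten a conjunction of comparisons; None if not such a form."""
    if isinstance(node, Binary) and node.op == "&&":
        left = _conjunction_leaves(node.left)
        right = _conjunction_leaves(node.right)
        if left is None or right is None:
            return None
        return left + right
    return [node]


def _enable_when(leaf: Node) -> Optional[dict]:
    if isinstance(leaf, Call) and leaf.fn == "has" and len(leaf.args) == 2:
        var, code = leaf.args
        if isinstance(var, Var) and isinstance(code, Lit):
            return {
                "question": var.name,
                "operator": "=",
                "answerCoding": {"code": str(code.value)},
            }
        return None
    if not (isinstance(leaf, Binary) and leaf.op in _FHIR_OPERATORS):
        return None
    left, right, op = leaf.left, leaf.right, leaf.op
    if isinstance(right, Var) and isinstance(left, Lit):
        # normalize "2 < q1" to "q1 > 2"
        flip = {"<": ">", "<=": ">=", ">": "<", ">=": "<=", "==": "==", "!=": "!="}
        left, right, op = right, left, flip[op]
    if not (isinstance(left, Var) and isinstance(right, Lit)):
        return None
    entry: dict[str, Any] = {"question": left.name, "operator": _FHIR_OPERATORS[op]}
    v = right.value
    if isinstance(v, bool):
        entry["answerBoolean"] = v
    elif isinstance(v, int):
        entry["answerInteger"] = v
    elif isinstance(v, float):
        entry["answerDecimal"] = v
    else:
        entry["answerString"] = v
    return entry


def to_fhir_questionnaire(activity: Activity, protocol: Protocol) -> dict:
    """Render one activity as a FHIR R4 Questionnaire resource (plain JSON).

    Visibility expressions that are conjunctions of single-variable
    comparisons become ``enableWhen`` entries with ``enableBehavior: all``;
    anything richer is omitted with a logged warning and recorded in an
    extension note on the item.
    """
    lang = protocol.default_language
    resource: dict[str, Any] = {
        "resourceType": "Questionnaire",
        "id": activity.name,
        "url": activity.id.iri() if activity.id.base else None,
        "version": activity.id.version if activity.id.base else None,
        "status": "active",
        "title": activity.pref_label.get(lang),
        "item": [],
    }
    resource = {k: v for k, v in resource.items() if v is not None}

    for ref in activity.item_order:
        item = ref.item
        entry: dict[str, Any] = {
            "linkId": ref.variable_name,
            "text": item.question.get(lang),
            "type": _FHIR_TYPE[item.input_type],
        }
        if ref.required:
            entry["required"] = True
        opts = item.response_options
        if opts is not None and opts.choices and entry["type"] == "choice":
            entry["answerOption"] = [
                {
                    "valueCoding": {
                        "code": str(c.value),
                        "display": c.label.get(lang),
                    }
                }
                for c in opts.choices
            ]
            if opts.multiple_choice:
                entry["repeats"] = True
        if ref.visibility is not None:
            leaves = _conjunction_leaves(parse_expression(ref.visibility).ast)
            clauses = [_enable_when(l) for l in leaves] if leaves else None
            if clauses is not None and all(c is not None for c in clauses):
                entry["enableWhen"] = clauses
                if len(clauses) > 1:
                    entry["enableBehavior"] = "all"
            else:
                logger.warning(
                    "item %s: visibility %r is not expressible as enableWhen; omitted",
                    ref.variable_name,
                    ref.visibility,
                )
                entry.setdefault("extension", []).append(
                    {"url": UNTRANSLATABLE_VIS_EXT, "valueString": ref.visibility}
                )
        resource["item"].append(entry)
    return resource


def check_fhir_questionnaire(resource: dict) -> list[str]:
    """Internal structural checker; returns a list of problems (empty = ok)."""
    problems = []
    if resource.get("resourceType") != "Questionnaire":
        problems.append("resourceType must be 'Questionnaire'")
    if not resource.get("status"):
        problems.append("status is required")
    link_ids = [i.get("linkId") for i in resource.get("item", [])]
    if any(not l for l in link_ids):
        problems.append("every item needs a linkId")
    if len(link_ids) != len(set(link_ids)):
        problems.append("item linkIds must be unique")
    known = set(link_ids)
    for i in resource.get("item", []):
        if i.get("type") == "choice" and not i.get("answerOption"):
            problems.append(f"choice item {i.get('linkId')!r} lacks answerOption")
        for ew in i.get("enableWhen", []):
            if ew.get("question") not in known:
                problems.append(
                    f"enableWhen on {i.get('linkId')!r} references unknown question "
                    f"{ew.get('question')!r}"
                )
            if not any(k.startswith("answer") for k in ew):
                problems.append(f"enableWhen on {i.get('linkId')!r} lacks an answer[x]")
    return problems


# ---------------------------------------------------------------------------
# BIDS phenotype
# ---------------------------------------------------------------------------

def _bindings_by_respondent(records: list[ResponseRecord], activity: Activity) -> dict[str, dict]:
    wanted = set(activity.variable_names())
    out: dict[str, dict] = {}
    missing_codes = {
        ref.variable_name: (ref.item.response_options.missing_codes
                            if ref.item.response_options else [])
        for ref in activity.item_order
    }
    for rec in records:
        if rec.variable_name not in wanted:
            continue
        slot = out.setdefault(rec.respondent, {})
        if rec.value in missing_codes.get(rec.variable_name, []):
            slot[rec.variable_name] = MISSING
        else:
            slot[rec.variable_name] = rec.value
    return out


def _cell(value: Any) -> Any:
    if value is MISSING or value is None:
        return "n/a"
    if isinstance(value, list):
        return ";".join(str(v) for v in value)
    return value


def to_bids_phenotype(protocol: Protocol, records: list[ResponseRecord],
                      out_dir: Union[str, Path]) -> list[Path]:
    """Write per-activity ``<name>.tsv`` + ``<name>.json`` sidecar.

    Column order: ``participant_id``, item variables in declared order,
    then computed variables. Missing/hidden cells are written as ``n/a``
    (BIDS convention). Computed columns are flagged ``"Derivative": true``
    in the sidecar.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lang = protocol.default_language
    written = []

    respondents = sorted({r.respondent for r in records})
    for act in protocol.activities():
        item_vars = [
            ref.variable_name
            for ref in act.item_order
            if ref.item.input_type != "static_display"
        ]
        computed = [r.target for r in act.compute_rules]
        columns = ["participant_id"] + item_vars + computed

        per_resp = _bindings_by_respondent(records, act)
        rows = []
        for resp in respondents:
            bindings = dict(per_resp.get(resp, {}))
            scored = compute_scores(act, bindings)
            row = [resp] + [_cell(bindings.get(v, MISSING)) for v in item_vars]
            row += [_cell(scored.get(t, MISSING)) for t in computed]
            rows.append(row)

        frame = pd.DataFrame(rows, columns=columns)
        tsv_path = out / f"{act.name}.tsv"
        frame.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")

        sidecar: dict[str, Any] = {}
        for ref in act.item_order:
            if ref.item.input_type == "static_display":
                continue
            entry: dict[str, Any] = {"Description": ref.item.question.get(lang)}
            opts = ref.item.response_options
            if opts is not None and opts.choices:
                entry["Levels"] = {str(c.value): c.label.get(lang) for c in opts.choices}
            if opts is not None and "units" in ref.item.extras:
                entry["Units"] = ref.item.extras["units"]
            sidecar[ref.variable_name] = entry
        for rule in act.compute_rules:
            sidecar[rule.target] = {
                "Description": f"Derived score: {rule.expression}",
                "Derivative": True,
            }
        json_path = out / f"{act.name}.json"
        write_canonical(json_path, sidecar)
        written.extend([tsv_path, json_path])
    return written


# ---------------------------------------------------------------------------
# Common data elements (flat submission table)
# ---------------------------------------------------------------------------

@dataclass
class CdeMapping:
    """User-supplied mapping from graph variables to a submission template.

    ``items`` maps variable name -> template element name; ``sources`` may
    name graph variables feeding the fixed metadata columns ``interview_age``
    and ``sex``. ``subjectkey`` and ``interview_date`` are always derived
    from the respondent id and the latest answer timestamp.
    """

    template: str
    activity: str
    items: dict[str, str]
    sources: dict[str, str] = field(default_factory=dict)

    FIXED_COLUMNS = ("subjectkey", "interview_date", "interview_age", "sex")

    @classmethod
    def from_yaml(cls, source: Union[str, Path, io.TextIOBase]) -> "CdeMapping":
        if isinstance(source, (str, Path)):
            raw = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
        else:
            raw = yaml.safe_load(source)
        return cls(
            template=raw["template"],
            activity=raw["activity"],
            items=dict(raw.get("items", {})),
            sources=dict(raw.get("sources", {})),
        )

    def validate_against(self, protocol: Protocol) -> None:
        act = protocol.get_activity(self.activity)
        if act is None:
            raise ConfigurationError(f"mapping names unknown activity {self.activity!r}")
        known = set(act.variable_names()) | {r.target for r in act.compute_rules}
        unknown = sorted((set(self.items) | set(self.sources.values())) - known)
        if unknown:
            raise ConfigurationError(
                f"mapping references variables absent from the graph: {unknown}"
            )
        names = list(self.items.values())
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate element names in mapping")


def to_cde(records: list[ResponseRecord], protocol: Protocol,
           mapping: CdeMapping) -> tuple[str, list[str]]:
    """Flatten responses into one CSV row per respondent for one template.

    Returns ``(csv_text, warnings)``; unmapped activity items are excluded
    with a warning, and each missing answer for a mapped element adds one.
    """
    mapping.validate_against(protocol)
    act = protocol.get_activity(mapping.activity)
    warnings: list[str] = []

    item_vars = [
        ref.variable_name
        for ref in act.item_order
        if ref.item.input_type != "static_display"
    ]
    unmapped = [v for v in item_vars if v not in mapping.items]
    if unmapped:
        warnings.append(f"unmapped items excluded: {', '.join(unmapped)}")

    per_resp = _bindings_by_respondent(records, act)
    dates: dict[str, str] = {}
    for rec in records:
        if rec.variable_name in set(item_vars):
            day = rec.answered_at.split("T")[0]
            if rec.respondent not in dates or day > dates[rec.respondent]:
                dates[rec.respondent] = day

    ordered_vars = [v for v in item_vars if v in mapping.items]
    ordered_vars += [v for v in mapping.items if v not in ordered_vars]  # computed
    columns = list(CdeMapping.FIXED_COLUMNS) + [mapping.items[v] for v in ordered_vars]

    rows = []
    for resp in sorted(per_resp):
        bindings = compute_scores(act, dict(per_resp[resp]))
        fixed = {
            "subjectkey": resp,
            "interview_date": dates.get(resp, ""),
            "interview_age": "",
            "sex": "",
        }
        for col in ("interview_age", "sex"):
            src = mapping.sources.get(col)
            if src is not None and bindings.get(src, MISSING) is not MISSING:
                fixed[col] = bindings[src]
        row = [fixed[c] for c in CdeMapping.FIXED_COLUMNS]
        for var in ordered_vars:
            value = bindings.get(var, MISSING)
            if value is MISSING:
                warnings.append(
                    f"respondent {resp}: no answer for mapped element "
                    f"{mapping.items[var]!r}"
                )
                row.append("")
            else:
                row.append(_cell(value))
        rows.append(row)

    import csv as _csv

    buf = io.StringIO()
    writer = _csv.writer(buf, lineterminator="\n")
    writer.writerow(columns)
    writer.writerows(rows)
    return buf.getvalue(), warnings
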