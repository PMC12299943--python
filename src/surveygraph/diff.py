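"""Semantic, classified diffing of two protocol versions.

Items are matched across versions by variable name (a renamed variable shows
up as removed + added). Expressions are compared at AST level with numeric
literal normalization, so whitespace-only or ``2`` vs ``2.0`` edits are not
reported. Change classes:

* ``item_added`` / ``item_removed`` — variable present in only one version
* ``wording`` — question or choice-label text differs (after whitespace
  normalization); changes confined to a non-default language carry the
  language code in the summary
* ``response_scale`` — choice set (values/cardinality) or numeric bounds
  differ; the summary gives the cardinality, e.g. ``5 -> 7 options``
* ``logic`` — visibility expression ASTs differ
* ``scoring`` — compute-rule ASTs or targets differ
* ``reordered`` — same variables, different relative order
* ``metadata`` — protocol name/description/license, activity label
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional

from .expr import Binary, Call, Lit, Node, Unary, Var, parse_expression
from .model import Activity, Item, ItemRef, LanguageMap, Protocol, VersionedId

CHANGE_CLASSES = (
    "item_added",
    "item_removed",
    "wording",
    "response_scale",
    "logic",
    "scoring",
    "reordered",
    "metadata",
)


@dataclass(frozen=True)
class ChangeEntry:
    path: str
    change_class: str
    before_summary: str
    after_summary: str

    @property
    def summary(self) -> str:
        """Combined before/after summary, e.g. ``5 → 7 options``."""
        m1 = re.match(r"^(\d+) options$", self.before_summary)
        m2 = re.match(r"^(\d+) options$", self.after_summary)
        if m1 and m2:
            return f"{m1.group(1)} → {m2.group(1)} options"
        return f"{self.before_summary} → {self.after_summary}"


@dataclass
class ChangeReport:
    old_version: VersionedId
    new_version: VersionedId
    entries: list[ChangeEntry] = field(default_factory=list)

    def by_class(self, change_class: str) -> list[ChangeEntry]:
        return [e for e in self.entries if e.change_class == change_class]


# ---------------------------------------------------------------------------
# Expression equivalence (AST with numeric-literal normalization)
# ---------------------------------------------------------------------------

def _norm_ast(node: Node):
    if isinstance(node, Lit):
        v = node.value
        if isinstance(v, bool):
            return ("lit", "bool", v)
        if isinstance(v, (int, float)):
            return ("lit", "num", float(v))
        return ("lit", "str", v)
    if isinstance(node, Var):
        return ("var", node.name)
    if isinstance(node, Unary):
        return ("unary", node.op, _norm_ast(node.operand))
    if isinstance(node, Binary):
        return ("binary", node.op, _norm_ast(node.left), _norm_ast(node.right))
    if isinstance(node, Call):
        return ("call", node.fn, tuple(_norm_ast(a) for a in node.args))
    raise TypeError(node)


def _expr_equal(a: Optional[str], b: Optional[str]) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return _norm_ast(parse_expression(a).ast) == _norm_ast(parse_expression(b).ast)


def _norm_ws(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


def _lm_diff_langs(a: LanguageMap, b: LanguageMap) -> list[str]:
    langs = sorted(set(a.entries) | set(b.entries))
    return [
        lang
        for lang in langs
        if _norm_ws(a.entries.get(lang, "")) != _norm_ws(b.entries.get(lang, ""))
    ]


# ---------------------------------------------------------------------------
# Diffing
# ---------------------------------------------------------------------------

def diff_protocols(old: Protocol, new: Protocol) -> ChangeReport:
    entries: list[ChangeEntry] = []

    for attr in ("name", "description"):
        diff_langs = _lm_diff_langs(getattr(old, attr), getattr(new, attr))
        if diff_langs:
            entries.append(
                ChangeEntry(
                    path=f"protocol/{attr}",
                    change_class="metadata",
                    before_summary=getattr(old, attr).get(old.default_language),
                    after_summary=getattr(new, attr).get(new.default_language),
                )
            )
    if old.license != new.license:
        entries.append(
            ChangeEntry("protocol/license", "metadata", old.license, new.license)
        )
    if old.schema_version != new.schema_version:
        entries.append(
            ChangeEntry("protocol/schemaVersion", "metadata", old.schema_version, new.schema_version)
        )

    old_acts = {r.name: r for r in old.activity_order}
    new_acts = {r.name: r for r in new.activity_order}
    for name in sorted(set(old_acts) | set(new_acts)):
        if name not in new_acts:
            for iref in old_acts[name].activity.item_order:
                entries.append(
                    ChangeEntry(
                        f"activities/{name}/items/{iref.variable_name}",
                        "item_removed",
                        _item_summary(iref),
                        "",
                    )
                )
            continue
        if name not in old_acts:
            for iref in new_acts[name].activity.item_order:
                entries.append(
                    ChangeEntry(
                        f"activities/{name}/items/{iref.variable_name}",
                        "item_added",
                        "",
                        _item_summary(iref),
                    )
                )
            continue
        entries.extend(_diff_activity(old_acts[name], new_acts[name], old, new))

    entries.sort(key=lambda e: (e.path, e.change_class))
    return ChangeReport(old_version=old.id, new_version=new.id, entries=entries)


def _item_summary(iref: ItemRef) -> str:
    item = iref.item
    n = len(item.response_options.choices) if item.response_options else 0
    extra = f", {n} options" if n else ""
    return f"{item.input_type} item {iref.variable_name!r}{extra}"


def _diff_activity(old_ref, new_ref, old_p: Protocol, new_p: Protocol) -> list[ChangeEntry]:
    name = old_ref.name
    base = f"activities/{name}"
    entries: list[ChangeEntry] = []
    old_act: Activity = old_ref.activity
    new_act: Activity = new_ref.activity

    if _lm_diff_langs(old_act.pref_label, new_act.pref_label):
        entries.append(
            ChangeEntry(
                f"{base}/prefLabel",
                "metadata",
                old_act.pref_label.get(old_p.default_language),
                new_act.pref_label.get(new_p.default_language),
            )
        )

    if not _expr_equal(old_ref.visibility, new_ref.visibility):
        entries.append(
            ChangeEntry(
                f"{base}/isVis",
                "logic",
                old_ref.visibility or "(always visible)",
                new_ref.visibility or "(always visible)",
            )
        )

    old_vars = old_act.variable_names()
    new_vars = new_act.variable_names()
    old_set, new_set = set(old_vars), set(new_vars)

    for var in sorted(old_set - new_set):
        entries.append(
            ChangeEntry(
                f"{base}/items/{var}",
                "item_removed",
                _item_summary(old_act.get_item_ref(var)),
                "",
            )
        )
    for var in sorted(new_set - old_set):
        entries.append(
            ChangeEntry(
                f"{base}/items/{var}",
                "item_added",
                "",
                _item_summary(new_act.get_item_ref(var)),
            )
        )

    common = old_set & new_set
    old_common = [v for v in old_vars if v in common]
    new_common = [v for v in new_vars if v in common]
    if old_common != new_common:
        entries.append(
            ChangeEntry(
                f"{base}/itemOrder",
                "reordered",
                ", ".join(old_common),
                ", ".join(new_common),
            )
        )

    for var in sorted(common):
        entries.extend(
            _diff_item(
                old_act.get_item_ref(var),
                new_act.get_item_ref(var),
                f"{base}/items/{var}",
                old_p.default_language,
            )
        )

    entries.extend(_diff_rules(old_act, new_act, base))
    return entries


def _diff_item(old: ItemRef, new: ItemRef, path: str, default_lang: str) -> list[ChangeEntry]:
    entries: list[ChangeEntry] = []

    q_langs = _lm_diff_langs(old.item.question, new.item.question)
    label_langs: list[str] = []
    oo, no = old.item.response_options, new.item.response_options

    scale_changed = False
    before_scale = after_scale = ""
    if (oo is None) != (no is None):
        scale_changed = True
        before_scale = "no options" if oo is None else _scale_summary(oo)
        after_scale = "no options" if no is None else _scale_summary(no)
    elif oo is not None and no is not None:
        old_values = [repr(c.value) for c in oo.choices]
        new_values = [repr(c.value) for c in no.choices]
        if (
            old_values != new_values
            or oo.min_value != no.min_value
            or oo.max_value != no.max_value
            or oo.value_type != no.value_type
            or oo.multiple_choice != no.multiple_choice
            or list(oo.missing_codes) != list(no.missing_codes)
        ):
            scale_changed = True
            before_scale = _scale_summary(oo)
            after_scale = _scale_summary(no)
        else:
            for oc, nc in zip(oo.choices, no.choices):
                label_langs.extend(_lm_diff_langs(oc.label, nc.label))

    if q_langs or label_langs:
        langs = sorted(set(q_langs) | set(label_langs))
        note = "" if langs == [default_lang] else f" [{', '.join(langs)}]"
        entries.append(
            ChangeEntry(
                path,
                "wording",
                old.item.question.get(default_lang) + note,
                new.item.question.get(default_lang) + note,
            )
        )
    if scale_changed:
        entries.append(ChangeEntry(path, "response_scale", before_scale, after_scale))
    if old.item.input_type != new.item.input_type:
        entries.append(
            ChangeEntry(path, "response_scale", old.item.input_type, new.item.input_type)
        )
    if not _expr_equal(old.visibility, new.visibility):
        entries.append(
            ChangeEntry(
                path,
                "logic",
                old.visibility or "(always visible)",
                new.visibility or "(always visible)",
            )
        )
    if old.required != new.required:
        entries.append(
            ChangeEntry(path, "metadata", f"required={old.required}", f"required={new.required}")
        )
    return entries


def _scale_summary(opts) -> str:
    if opts.choices:
        return f"{len(opts.choices)} options"
    if opts.min_value is not None or opts.max_value is not None:
        return f"range [{opts.min_value}, {opts.max_value}]"
    return opts.value_type


def _diff_rules(old_act: Activity, new_act: Activity, base: str) -> list[ChangeEntry]:
    entries = []
    old_rules = {r.target: r.expression for r in old_act.compute_rules}
    new_rules = {r.target: r.expression for r in new_act.compute_rules}
    for target in sorted(set(old_rules) | set(new_rules)):
        path = f"{base}/computeRules/{target}"
        if target not in new_rules:
            entries.append(ChangeEntry(path, "scoring", old_rules[target], "(removed)"))
        elif target not in old_rules:
            entries.append(ChangeEntry(path, "scoring", "(absent)", new_rules[target]))
        elif not _expr_equal(old_rules[target], new_rules[target]):
            entries.append(ChangeEntry(path, "scoring", old_rules[target], new_rules[target]))
    return entries


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_report(report: ChangeReport, fmt: str = "text") -> str:
    """Deterministic rendering; ``text`` or ``jsonl``."""
    if fmt == "text":
        if not report.entries:
            return "no changes\n"
        lines = [
            f"{report.old_version.version} -> {report.new_version.version}: "
            f"{len(report.entries)} change(s)"
        ]
        for e in report.entries:
            lines.append(
                f"  [{e.change_class}] {e.path}: {e.before_summary!r} -> {e.after_summary!r}"
            )
        return "\n".join(lines) + "\n"
    if fmt == "jsonl":
        lines = [
            json.dumps(
                {
                    "path": e.path,
                    "change_class": e.change_class,
                    "before": e.before_summary,
                    "after": e.after_summary,
                },
                sort_keys=True,
            )
            for e in report.entries
        ]
        return "\n".join(lines) + ("\n" if lines else "")
    raise ValueError(f"unknown format {fmt!r}")
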