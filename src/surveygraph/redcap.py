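"""Bidirectional conversion between REDCap data dictionaries and the schema graph.

Import maps each form to an activity and each field row to an item (``calc``
rows become compute rules, ``descriptive`` rows and section headers become
static-display items). Branching logic is translated between REDCap syntax
(``[var]``, ``=``, ``<>``, ``and``/``or``, ``[var(3)] = '1'`` checkbox tests)
and the package's expression language.

Export is the inverse on the supported subset: round-tripping a dictionary
through import and back reproduces it after cell trimming and canonical
``and``/``or`` case. REDCap-only metadata (field notes, matrix groups,
annotations) is carried through as opaque item extras so it survives the
round trip even though it is not modelled.

Dialect: comma-separated, double-quote quoting, UTF-8; CRLF line endings and
an optional BOM are tolerated on input.
"""

from __future__ import annotations

import csv
import io
import re
from pathlib import Path
from typing import Any, Optional, Union

from .expr import (
    Binary,
    Call,
    Expression,
    ExpressionError,
    Lit,
    Node,
    Unary,
    Var,
    parse_expression,
    serialize,
)
from .model import (
    Activity,
    ActivityRef,
    Choice,
    Item,
    ItemRef,
    ComputeRule,
    LanguageMap,
    Protocol,
    ResponseOptions,
    ResponseRecord,
)
from .storage import pin_versions

HEADERS = (
    "Variable / Field Name",
    "Form Name",
    "Section Header",
    "Field Type",
    "Field Label",
    "Choices, Calculations, OR Slider Labels",
    "Field Note",
    "Text Validation Type OR Show Slider Number",
    "Text Validation Min",
    "Text Validation Max",
    "Identifier?",
    "Branching Logic (Show field only if...)",
    "Required Field?",
    "Custom Alignment",
    "Question Number (surveys only)",
    "Matrix Group Name",
    "Matrix Ranking?",
    "Field Annotation",
)

# columns carried through untouched as item extras
_PASSTHROUGH = (
    "Field Note",
    "Identifier?",
    "Custom Alignment",
    "Question Number (surveys only)",
    "Matrix Group Name",
    "Matrix Ranking?",
    "Field Annotation",
)


class ConversionError(ValueError):
    """A dictionary row cannot be converted; names the row/column."""


class TranslationError(ValueError):
    """A branching-logic fragment cannot be translated."""


class ExportError(ValueError):
    """A graph construct is not representable in a REDCap dictionary."""


# ---------------------------------------------------------------------------
# Branching-logic translation (REDCap -> expression language)
# ---------------------------------------------------------------------------

_QUOTED_SPLIT = re.compile(r"('(?:[^']*)')")


def _rewrite_checkbox_tests(text: str) -> str:
    # [var(code)] = '1' / <> '0' checkbox tests, rewritten before quote
    # handling since the pattern spans the quoted flag
    def checkbox_cmp(m: re.Match) -> str:
        var, code, op, flag = m.group(1), m.group(2), m.group(3), m.group(4)
        positive = (op == "=" and flag == "1") or (op == "<>" and flag == "0")
        call = f'has({var}, "{code}")'
        return call if positive else f"!{call}"

    return re.sub(r"\[(\w+)\((\w+)\)\]\s*(=|<>)\s*'([01])'", checkbox_cmp, text)


def _translate_fragment(text: str) -> str:
    text = re.sub(r"\[(\w+)\((\w+)\)\]", r'has(\1, "\2")', text)
    text = re.sub(r"\[(\w+)\]", r"\1", text)
    text = text.replace("<>", "!=")
    text = re.sub(r"(?<![<>!=])=(?!=)", "==", text)
    text = re.sub(r"\band\b", "&&", text, flags=re.IGNORECASE)
    text = re.sub(r"\bor\b", "||", text, flags=re.IGNORECASE)
    return text


def translate_branching(redcap_logic: str) -> Expression:
    """Translate REDCap logic syntax into a parsed :class:`Expression`."""
    parts = _QUOTED_SPLIT.split(_rewrite_checkbox_tests(redcap_logic))
    out = []
    for part in parts:
        if part.startswith("'") and part.endswith("'") and len(part) >= 2:
            body = part[1:-1].replace('"', '\\"')
            out.append(f'"{body}"')
        else:
            out.append(_translate_fragment(part))
    translated = "".join(out)
    try:
        ast = parse_expression(translated).ast
    except ExpressionError as exc:
        raise TranslationError(
            f"cannot translate REDCap logic {redcap_logic!r} "
            f"(became {translated!r}): {exc}"
        ) from exc
    canonical = serialize(ast)
    return parse_expression(canonical)


# ---------------------------------------------------------------------------
# Back-translation (expression language -> REDCap)
# ---------------------------------------------------------------------------

_OP_TO_REDCAP = {"==": "=", "!=": "<>", "&&": "and", "||": "or"}
_PREC = {
    "||": 1, "&&": 2,
    "==": 3, "!=": 3, "<": 3, "<=": 3, ">": 3, ">=": 3,
    "+": 4, "-": 4, "*": 5, "/": 5, "%": 5,
}


def _lower_aggregates(node: Node) -> Node:
    """Rewrite mean/sum calls as explicit arithmetic (REDCap calc has no
    aggregate functions); other aggregates are untranslatable."""
    if isinstance(node, Call):
        args = tuple(_lower_aggregates(a) for a in node.args)
        if node.fn in ("sum", "mean"):
            if not args:
                raise ExportError(f"{node.fn}() with no arguments is untranslatable")
            chain: Node = args[0]
            for a in args[1:]:
                chain = Binary("+", chain, a)
            if node.fn == "mean":
                return Binary("/", chain, Lit(len(args)))
            return chain
        return Call(node.fn, args)
    if isinstance(node, Binary):
        return Binary(node.op, _lower_aggregates(node.left), _lower_aggregates(node.right))
    if isinstance(node, Unary):
        return Unary(node.op, _lower_aggregates(node.operand))
    return node


def back_translate(expr: Union[Expression, Node], allow_arithmetic: bool = False) -> str:
    """Render an expression in REDCap syntax; raises :class:`ExportError`
    for constructs REDCap cannot express (aggregate calls in branching,
    sd/min/max/count/isMissing anywhere)."""
    node = expr.ast if isinstance(expr, Expression) else expr
    if allow_arithmetic:
        node = _lower_aggregates(node)
    return _bt(node, 0, allow_arithmetic)


def _bt(node: Node, parent_prec: int, arith: bool) -> str:
    if isinstance(node, Lit):
        v = node.value
        if isinstance(v, bool):
            raise ExportError("boolean literals are untranslatable to REDCap")
        if isinstance(v, str):
            return "'" + v.replace("'", "") + "'"
        if isinstance(v, float) and v.is_integer():
            return f"{v:.1f}"
        return repr(v)
    if isinstance(node, Var):
        return f"[{node.name}]"
    if isinstance(node, Call):
        if node.fn == "has" and len(node.args) == 2:
            return _bt_checkbox(node, positive=True)
        raise ExportError(f"function {node.fn}() is untranslatable to REDCap")
    if isinstance(node, Unary):
        if node.op == "!" and isinstance(node.operand, Call) and node.operand.fn == "has":
            return _bt_checkbox(node.operand, positive=False)
        if node.op == "-":
            return f"-{_bt(node.operand, _PREC['*'] + 1, arith)}"
        raise ExportError("logical negation is untranslatable to REDCap")
    if isinstance(node, Binary):
        op = node.op
        if op in ("+", "-", "*", "/", "%") and not arith:
            raise ExportError(f"arithmetic {op!r} not allowed in branching logic")
        prec = _PREC[op]
        left = _bt(node.left, prec, arith)
        right = _bt(node.right, prec + 1, arith)
        text = f"{left} {_OP_TO_REDCAP.get(op, op)} {right}"
        return f"({text})" if prec < parent_prec else text
    raise ExportError(f"untranslatable node {node!r}")


def _bt_checkbox(call: Call, positive: bool) -> str:
    var, code = call.args
    if not isinstance(var, Var) or not isinstance(code, Lit):
        raise ExportError("has() requires a variable and a literal code for REDCap export")
    code_text = code.value if isinstance(code.value, str) else repr(code.value)
    flag = "1" if positive else "0"
    return f"[{var.name}({code_text})] = '{flag}'"


# ---------------------------------------------------------------------------
# Choices strings
# ---------------------------------------------------------------------------

def _parse_code(text: str) -> Any:
    return int(text) if re.fullmatch(r"-?\d+", text) else text


def parse_choices(raw: str, row: int) -> list[Choice]:
    choices = []
    for part in raw.split("|"):
        part = part.strip()
        if not part:
            continue
        if "," not in part:
            raise ConversionError(
                f"row {row}: malformed choices entry {part!r} in "
                f"'Choices, Calculations, OR Slider Labels'"
            )
        code, label = part.split(",", 1)
        choices.append(Choice(_parse_code(code.strip()), LanguageMap.of(label.strip())))
    if not choices:
        raise ConversionError(f"row {row}: empty choices string")
    return choices


def format_choices(choices: list[Choice], lang: str = "en") -> str:
    return " | ".join(f"{c.value}, {c.label.get(lang)}" for c in choices)


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------

def read_dictionary(source: Union[str, Path, io.TextIOBase]) -> list[dict[str, str]]:
    """Read and structurally check a data-dictionary CSV (18-column header,
    unique variable names, forms contiguous)."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8-sig", newline="") as fh:
            return read_dictionary(fh)
    reader = csv.reader(source)
    try:
        header = next(reader)
    except StopIteration:
        raise ConversionError("empty dictionary file") from None
    header = [h.strip().lstrip("﻿") for h in header]
    if header != list(HEADERS):
        raise ConversionError(
            f"header does not match the 18-column data-dictionary template: {header!r}"
        )
    rows = []
    for raw in reader:
        if not any(cell.strip() for cell in raw):
            continue
        raw = list(raw) + [""] * (len(HEADERS) - len(raw))
        rows.append({h: raw[i].strip() for i, h in enumerate(HEADERS)})
    names = [r["Variable / Field Name"] for r in rows]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConversionError(f"duplicate variable names: {dupes}")
    seen_forms = []
    for r in rows:
        form = r["Form Name"]
        if seen_forms and form != seen_forms[-1] and form in seen_forms:
            raise ConversionError(f"form {form!r} rows are not contiguous")
        if not seen_forms or form != seen_forms[-1]:
            seen_forms.append(form)
    return rows


def _import_field(row: dict[str, str], idx: int) -> Item:
    ftype = row["Field Type"]
    label = LanguageMap.of(row["Field Label"] or row["Variable / Field Name"])
    validation = row["Text Validation Type OR Show Slider Number"]
    choices_raw = row["Choices, Calculations, OR Slider Labels"]
    extras: dict[str, Any] = {}
    for col in _PASSTHROUGH:
        if row[col]:
            extras[col] = row[col]

    def bounds():
        lo = row["Text Validation Min"]
        hi = row["Text Validation Max"]
        conv = float if validation == "number" else int
        return (conv(lo) if lo else None, conv(hi) if hi else None)

    if ftype in ("radio", "dropdown"):
        choices = parse_choices(choices_raw, idx)
        vt = "integer" if all(isinstance(c.value, int) for c in choices) else "code"
        options = ResponseOptions(value_type=vt, choices=choices)
        input_type = "radio" if ftype == "radio" else "select"
    elif ftype == "checkbox":
        choices = parse_choices(choices_raw, idx)
        vt = "integer" if all(isinstance(c.value, int) for c in choices) else "code"
        options = ResponseOptions(value_type=vt, choices=choices, multiple_choice=True)
        input_type = "multiselect"
    elif ftype == "yesno":
        options = ResponseOptions(
            value_type="integer",
            choices=[Choice(1, LanguageMap.of("Yes")), Choice(0, LanguageMap.of("No"))],
        )
        input_type = "radio"
        extras["redcap_field_type"] = "yesno"
    elif ftype == "truefalse":
        options = ResponseOptions(
            value_type="integer",
            choices=[Choice(1, LanguageMap.of("True")), Choice(0, LanguageMap.of("False"))],
        )
        input_type = "radio"
        extras["redcap_field_type"] = "truefalse"
    elif ftype == "text":
        if validation == "integer":
            lo, hi = bounds()
            options = ResponseOptions(value_type="integer", min_value=lo, max_value=hi)
            input_type = "integer"
        elif validation == "number":
            lo, hi = bounds()
            options = ResponseOptions(value_type="decimal", min_value=lo, max_value=hi)
            input_type = "decimal"
        elif validation.startswith("date"):
            options = ResponseOptions(value_type="string")
            input_type = "date"
            extras["redcap_validation"] = validation
        else:
            if validation:
                extras["redcap_validation"] = validation
            options = ResponseOptions(value_type="string")
            input_type = "text"
    elif ftype == "notes":
        options = ResponseOptions(value_type="string")
        input_type = "textarea"
    elif ftype == "slider":
        options = ResponseOptions(value_type="integer", min_value=0, max_value=100)
        input_type = "slider"
        if choices_raw:
            extras["slider_labels"] = choices_raw
        if validation:
            extras["redcap_validation"] = validation
    elif ftype == "descriptive":
        options = None
        input_type = "static_display"
    elif ftype == "file":
        options = None
        input_type = "file_upload"
    else:
        raise ConversionError(f"row {idx}: unknown field type {ftype!r}")

    return Item(
        name=row["Variable / Field Name"],
        question=label,
        input_type=input_type,
        response_options=options,
        extras=extras,
    )


def import_data_dictionary(source: Union[str, Path, io.TextIOBase]) -> Protocol:
    """Build a protocol graph from a data dictionary: one activity per form."""
    rows = read_dictionary(source)
    forms: dict[str, list[tuple[int, dict]]] = {}
    order: list[str] = []
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        form = row["Form Name"]
        if form not in forms:
            forms[form] = []
            order.append(form)
        forms[form].append((i, row))

    activity_refs = []
    for form in order:
        item_refs: list[ItemRef] = []
        rules: list[ComputeRule] = []
        for idx, row in forms[form]:
            var = row["Variable / Field Name"]
            if row["Section Header"]:
                item_refs.append(
                    ItemRef(
                        variable_name=f"{var}_sh",
                        item=Item(
                            name=f"{var}_sh",
                            question=LanguageMap.of(row["Section Header"]),
                            input_type="static_display",
                            extras={"redcap_section_header": True},
                        ),
                    )
                )
            if row["Field Type"] == "calc":
                expr = translate_branching(row["Choices, Calculations, OR Slider Labels"])
                rules.append(ComputeRule(target=var, expression=serialize(expr.ast)))
                continue
            visibility = None
            logic = row["Branching Logic (Show field only if...)"]
            if logic:
                visibility = serialize(translate_branching(logic).ast)
            item_refs.append(
                ItemRef(
                    variable_name=var,
                    item=_import_field(row, idx),
                    visibility=visibility,
                    required=row["Required Field?"].lower() == "y",
                )
            )
        activity_refs.append(
            ActivityRef(
                name=form,
                activity=Activity(
                    name=form,
                    pref_label=LanguageMap.of(form),
                    item_order=item_refs,
                    compute_rules=rules,
                ),
                required=True,
            )
        )

    protocol = Protocol(
        name=LanguageMap.of("Imported REDCap project"),
        description=LanguageMap.of("Converted from a REDCap data dictionary"),
        activity_order=activity_refs,
        base_iri="https://example.org/surveygraph/redcap-import",
    )
    pin_versions(protocol)
    return protocol


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _export_item_row(ref: ItemRef, form: str, lang: str) -> dict[str, str]:
    item = ref.item
    row = {h: "" for h in HEADERS}
    row["Variable / Field Name"] = ref.variable_name
    row["Form Name"] = form
    row["Field Label"] = item.question.get(lang)
    row["Required Field?"] = "y" if ref.required else ""
    for col in _PASSTHROUGH:
        if col in item.extras:
            row[col] = str(item.extras[col])
    opts = item.response_options
    it = item.input_type

    if it == "radio" and item.extras.get("redcap_field_type") in ("yesno", "truefalse"):
        row["Field Type"] = item.extras["redcap_field_type"]
    elif it in ("radio", "select", "multiselect"):
        row["Field Type"] = {"radio": "radio", "select": "dropdown", "multiselect": "checkbox"}[it]
        row["Choices, Calculations, OR Slider Labels"] = format_choices(opts.choices, lang)
    elif it in ("integer", "decimal"):
        row["Field Type"] = "text"
        row["Text Validation Type OR Show Slider Number"] = (
            "integer" if it == "integer" else "number"
        )
        if opts is not None:
            if opts.min_value is not None:
                row["Text Validation Min"] = _num_str(opts.min_value)
            if opts.max_value is not None:
                row["Text Validation Max"] = _num_str(opts.max_value)
    elif it == "text":
        row["Field Type"] = "text"
        if "redcap_validation" in item.extras:
            row["Text Validation Type OR Show Slider Number"] = item.extras["redcap_validation"]
    elif it == "date":
        row["Field Type"] = "text"
        row["Text Validation Type OR Show Slider Number"] = item.extras.get(
            "redcap_validation", "date_ymd"
        )
    elif it == "textarea":
        row["Field Type"] = "notes"
    elif it == "slider":
        row["Field Type"] = "slider"
        if "slider_labels" in item.extras:
            row["Choices, Calculations, OR Slider Labels"] = item.extras["slider_labels"]
        if "redcap_validation" in item.extras:
            row["Text Validation Type OR Show Slider Number"] = item.extras["redcap_validation"]
    elif it == "static_display":
        row["Field Type"] = "descriptive"
    elif it == "file_upload":
        row["Field Type"] = "file"
    else:
        raise ExportError(f"item {ref.variable_name!r}: input type {it!r} has no REDCap equivalent")

    if ref.visibility is not None:
        try:
            row["Branching Logic (Show field only if...)"] = back_translate(
                parse_expression(ref.visibility)
            )
        except ExportError as exc:
            raise ExportError(f"item {ref.variable_name!r}: {exc}") from exc
    return row


def _num_str(v) -> str:
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def export_data_dictionary(protocol: Protocol, target: Union[str, Path, io.TextIOBase, None] = None) -> str:
    """Render the graph as a data-dictionary CSV; returns the CSV text."""
    lang = protocol.default_language
    out_rows: list[dict[str, str]] = []
    for aref in protocol.activity_order:
        act = aref.activity
        pending_header: Optional[str] = None
        for ref in act.item_order:
            if ref.item.extras.get("redcap_section_header"):
                pending_header = ref.item.question.get(lang)
                continue
            row = _export_item_row(ref, aref.name, lang)
            if pending_header is not None:
                row["Section Header"] = pending_header
                pending_header = None
            out_rows.append(row)
        if pending_header is not None:
            raise ExportError(
                f"activity {act.name!r}: trailing section header has no following field"
            )
        for rule in act.compute_rules:
            row = {h: "" for h in HEADERS}
            row["Variable / Field Name"] = rule.target
            row["Form Name"] = aref.name
            row["Field Type"] = "calc"
            row["Field Label"] = rule.target
            try:
                row["Choices, Calculations, OR Slider Labels"] = back_translate(
                    parse_expression(rule.expression), allow_arithmetic=True
                )
            except ExportError as exc:
                raise ExportError(f"compute rule {rule.target!r}: {exc}") from exc
            out_rows.append(row)

    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=list(HEADERS), lineterminator="\n")
    writer.writeheader()
    writer.writerows(out_rows)
    text = buf.getvalue()
    if isinstance(target, (str, Path)):
        Path(target).write_text(text, encoding="utf-8")
    elif target is not None:
        target.write(text)
    return text


# ---------------------------------------------------------------------------
# Response export (wide CSV, REDCap conventions)
# ---------------------------------------------------------------------------

def export_responses(records: list[ResponseRecord], protocol: Protocol,
                     target: Union[str, Path, io.TextIOBase, None] = None) -> str:
    """One row per respondent, one column per variable; multiselects expand
    to ``var___code`` 0/1 indicator columns; hidden or unanswered cells stay
    empty (never 0)."""
    columns = ["record_id"]
    multiselect_codes: dict[str, list] = {}
    for act in protocol.activities():
        for ref in act.item_order:
            if ref.item.input_type == "static_display":
                continue
            opts = ref.item.response_options
            if opts is not None and opts.multiple_choice:
                codes = opts.choice_values()
                multiselect_codes[ref.variable_name] = codes
                columns.extend(f"{ref.variable_name}___{c}" for c in codes)
            else:
                columns.append(ref.variable_name)

    by_respondent: dict[str, dict[str, Any]] = {}
    for rec in records:
        by_respondent.setdefault(rec.respondent, {})[rec.variable_name] = rec.value

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(columns)
    for respondent in sorted(by_respondent):
        answers = by_respondent[respondent]
        row: list[Any] = [respondent]
        for col in columns[1:]:
            if "___" in col:
                var, code = col.rsplit("___", 1)
                if var in answers and isinstance(answers[var], list):
                    row.append(1 if any(str(v) == code for v in answers[var]) else 0)
                else:
                    row.append("")  # hidden/unanswered: empty, not 0
            else:
                row.append(answers.get(col, ""))
        writer.writerow(row)
    text = buf.getvalue()
    if isinstance(target, (str, Path)):
        Path(target).write_text(text, encoding="utf-8")
    elif target is not None:
        target.write(text)
    return text
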