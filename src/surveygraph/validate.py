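"""Structural and semantic validation of protocol graphs and response values.

Problems are reported as :class:`Finding` diagnostics, never exceptions, so a
single pass can report everything at once. Finding order is deterministic
(path, then code) to keep CLI output diffable.

Finding codes (closed set)
--------------------------
========================  ========  =====================================================
code                      severity  meaning
========================  ========  =====================================================
DANGLING_REF              error     reference to a node absent from the graph
DUP_VARNAME               error     duplicate variable name within an activity
SCORE_CYCLE               error     compute-rule dependency cycle
EXPR_UNKNOWN_VAR          error     expression references an undeclared variable
EXPR_SYNTAX               error     expression does not parse
BOUNDS_ORDER              error     min_value greater than max_value
BAD_VARNAME               error     variable name not matching ``[A-Za-z][A-Za-z0-9_]*``
STATIC_OPTIONS            warning   static_display item carries response options
NONNUMERIC_OPTIONS        error     numeric input type without numeric value_type
RANGE_VIOLATION           error     numeric value outside [min_value, max_value]
VOCAB_VIOLATION           error     coded value outside the controlled choice set
TYPE_MISMATCH             error     value of the wrong type for the options
VERSION_MIX               warning   response set spans multiple protocol versions
========================  ========  =====================================================

Bounds are inclusive: an age constraint of 18–99 accepts both 18 and 99.
Declared missing codes always pass value validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Any, Optional

from .expr import ExpressionError, parse_expression
from .model import (
    Activity,
    NUMERIC_INPUT_TYPES,
    Protocol,
    ResponseOptions,
    ResponseRecord,
    VARNAME_RE,
)

ERROR = "error"
WARNING = "warning"

FINDING_CODES = frozenset(
    {
        "DANGLING_REF",
        "DUP_VARNAME",
        "SCORE_CYCLE",
        "EXPR_UNKNOWN_VAR",
        "EXPR_SYNTAX",
        "BOUNDS_ORDER",
        "BAD_VARNAME",
        "STATIC_OPTIONS",
        "NONNUMERIC_OPTIONS",
        "RANGE_VIOLATION",
        "VOCAB_VIOLATION",
        "TYPE_MISMATCH",
        "VERSION_MIX",
    }
)


@dataclass(frozen=True)
class Finding:
    severity: str
    code: str
    path: str
    message: str

    def __post_init__(self) -> None:
        assert self.code in FINDING_CODES, self.code

    def as_dict(self) -> dict:
        return {
            "severity": self.severity,
            "code": self.code,
            "path": self.path,
            "message": self.message,
        }


def _sorted(findings: list[Finding]) -> list[Finding]:
    return sorted(findings, key=lambda f: (f.path, f.code, f.message))


def has_errors(findings: list[Finding]) -> bool:
    return any(f.severity == ERROR for f in findings)


# ---------------------------------------------------------------------------
# Protocol graph validation
# ---------------------------------------------------------------------------

def validate_protocol(protocol: Protocol) -> list[Finding]:
    """An empty list means the graph satisfies every structural invariant:
    unique variable names, well-formed expressions referencing only declared
    variables, acyclic compute rules, and coherent response options."""
    findings: list[Finding] = []

    # variables computed anywhere are legal in activity-level visibility
    all_vars: set[str] = set()
    for act in protocol.activities():
        all_vars.update(act.variable_names())
        all_vars.update(r.target for r in act.compute_rules)

    for aref in protocol.activity_order:
        ppath = f"protocol/{aref.name}"
        if aref.visibility is not None:
            findings.extend(_check_expr(aref.visibility, all_vars, ppath + "/isVis"))
        findings.extend(_validate_activity(aref.activity, aref.name))

    return _sorted(findings)


def _validate_activity(act: Activity, name: str) -> list[Finding]:
    findings: list[Finding] = []
    base = f"activities/{name}"

    seen: set[str] = set()
    for ref in act.item_order:
        if ref.variable_name in seen:
            findings.append(
                Finding(
                    ERROR,
                    "DUP_VARNAME",
                    f"{base}/items/{ref.variable_name}",
                    f"duplicate variable name {ref.variable_name!r}",
                )
            )
        seen.add(ref.variable_name)

    declared = set(act.variable_names())
    targets = [r.target for r in act.compute_rules]
    for t in targets:
        if t in declared:
            findings.append(
                Finding(
                    ERROR,
                    "DUP_VARNAME",
                    f"{base}/computeRules/{t}",
                    f"compute target {t!r} collides with an item variable",
                )
            )
    scope = declared | set(targets)

    for ref in act.item_order:
        ipath = f"{base}/items/{ref.variable_name}"
        if not VARNAME_RE.match(ref.variable_name):
            findings.append(
                Finding(ERROR, "BAD_VARNAME", ipath, f"bad variable name {ref.variable_name!r}")
            )
        if ref.visibility is not None:
            findings.extend(_check_expr(ref.visibility, scope, ipath + "/isVis"))
        findings.extend(_validate_item_options(ref.item, ipath))

    rule_exprs = {}
    for rule in act.compute_rules:
        rpath = f"{base}/computeRules/{rule.target}"
        exprs = _check_expr(rule.expression, scope, rpath)
        findings.extend(exprs)
        if not exprs:
            rule_exprs[rule.target] = parse_expression(rule.expression)

    # cycle detection over rule-to-rule dependencies
    graph = {
        t: {d for d in e.refs if d in rule_exprs} for t, e in rule_exprs.items()
    }
    try:
        list(TopologicalSorter(graph).static_order())
    except CycleError as exc:
        cyclic = sorted(v for v in exc.args[1] if v in rule_exprs)
        findings.append(
            Finding(
                ERROR,
                "SCORE_CYCLE",
                f"{base}/computeRules",
                f"compute-rule cycle involving {cyclic}",
            )
        )
    return findings


def _check_expr(source: str, scope: set[str], path: str) -> list[Finding]:
    try:
        expr = parse_expression(source)
    except ExpressionError as exc:
        return [Finding(ERROR, "EXPR_SYNTAX", path, f"cannot parse {source!r}: {exc}")]
    unknown = sorted(expr.refs - scope)
    return [
        Finding(ERROR, "EXPR_UNKNOWN_VAR", path, f"unknown variable {v!r} in {source!r}")
        for v in unknown
    ]


def _validate_item_options(item, ipath: str) -> list[Finding]:
    findings = []
    opts = item.response_options
    if item.input_type == "static_display":
        if opts is not None:
            findings.append(
                Finding(WARNING, "STATIC_OPTIONS", ipath, "static_display item has response options")
            )
        return findings
    if opts is None:
        return findings
    if item.input_type in NUMERIC_INPUT_TYPES and opts.value_type not in ("integer", "decimal"):
        findings.append(
            Finding(
                ERROR,
                "NONNUMERIC_OPTIONS",
                ipath,
                f"{item.input_type} item requires numeric value_type, got {opts.value_type!r}",
            )
        )
    if (
        opts.min_value is not None
        and opts.max_value is not None
        and opts.min_value > opts.max_value
    ):
        findings.append(
            Finding(
                ERROR,
                "BOUNDS_ORDER",
                ipath,
                f"min_value {opts.min_value} exceeds max_value {opts.max_value}",
            )
        )
    return findings


# ---------------------------------------------------------------------------
# Response-value validation
# ---------------------------------------------------------------------------

def _is_number(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def validate_response(value: Any, options: ResponseOptions, path: str = "value") -> list[Finding]:
    """Check one value against its options. Inclusive numeric bounds;
    controlled-vocabulary membership for coded values; element-wise checks
    for multiselect lists; declared missing codes always pass."""
    if value in _missing_set(options):
        return []
    if options.multiple_choice:
        if not isinstance(value, list):
            return [
                Finding(ERROR, "TYPE_MISMATCH", path, f"multiselect value must be a list, got {value!r}")
            ]
        out = []
        for i, v in enumerate(value):
            out.extend(_validate_scalar(v, options, f"{path}[{i}]"))
        return _sorted(out)
    return _sorted(_validate_scalar(value, options, path))


def _missing_set(options: ResponseOptions) -> list:
    return options.missing_codes


def _validate_scalar(value: Any, options: ResponseOptions, path: str) -> list[Finding]:
    vt = options.value_type
    if vt == "integer":
        if not isinstance(value, int) or isinstance(value, bool):
            return [Finding(ERROR, "TYPE_MISMATCH", path, f"expected integer, got {value!r}")]
    elif vt == "decimal":
        if not _is_number(value):
            return [Finding(ERROR, "TYPE_MISMATCH", path, f"expected number, got {value!r}")]
    elif vt in ("string", "code"):
        if options.choices:
            # coded choice sets may legitimately use numeric codes
            if not isinstance(value, (str, int, float)) or isinstance(value, bool):
                return [Finding(ERROR, "TYPE_MISMATCH", path, f"expected code, got {value!r}")]
        elif not isinstance(value, str):
            return [Finding(ERROR, "TYPE_MISMATCH", path, f"expected string, got {value!r}")]

    findings = []
    if options.choices:
        allowed = options.choice_values()
        if not any(_code_equal(value, a) for a in allowed):
            # numeric scales report a range problem; string vocabularies a
            # controlled-vocabulary problem
            if _is_number(value) and all(_is_number(a) for a in allowed):
                findings.append(
                    Finding(
                        ERROR,
                        "RANGE_VIOLATION",
                        path,
                        f"value {value!r} outside the response scale {allowed!r}",
                    )
                )
            else:
                findings.append(
                    Finding(
                        ERROR,
                        "VOCAB_VIOLATION",
                        path,
                        f"value {value!r} not in controlled vocabulary {allowed!r}",
                    )
                )
    if _is_number(value):
        if options.min_value is not None and value < options.min_value:
            findings.append(
                Finding(ERROR, "RANGE_VIOLATION", path, f"value {value!r} below minimum {options.min_value}")
            )
        if options.max_value is not None and value > options.max_value:
            findings.append(
                Finding(ERROR, "RANGE_VIOLATION", path, f"value {value!r} above maximum {options.max_value}")
            )
    return findings


def _code_equal(a: Any, b: Any) -> bool:
    if _is_number(a) and _is_number(b):
        return float(a) == float(b)
    return a == b


# ---------------------------------------------------------------------------
# Record validation
# ---------------------------------------------------------------------------

def validate_records(records: list[ResponseRecord], protocol: Protocol) -> list[Finding]:
    """Per-record value validation plus provenance consistency checks."""
    findings: list[Finding] = []

    item_index: dict[str, tuple[str, ResponseOptions | None]] = {}
    for aref in protocol.activity_order:
        for iref in aref.activity.item_order:
            item_index[iref.item.id.iri()] = (
                f"activities/{aref.name}/items/{iref.variable_name}",
                iref.item.response_options,
            )

    protocol_versions = set()
    for i, rec in enumerate(records):
        rpath = f"records/{rec.respondent}/{rec.variable_name}"
        protocol_versions.add(rec.protocol_id.version)
        entry = item_index.get(rec.item_id.iri())
        if entry is None:
            findings.append(
                Finding(
                    ERROR,
                    "DANGLING_REF",
                    rpath,
                    f"record references item {rec.item_id.iri()} absent from the graph",
                )
            )
            continue
        ipath, options = entry
        if options is not None:
            for f in validate_response(rec.value, options, rpath):
                findings.append(f)

    if len(protocol_versions) > 1:
        findings.append(
            Finding(
                WARNING,
                "VERSION_MIX",
                "records",
                f"response set spans {len(protocol_versions)} protocol versions: "
                f"{sorted(protocol_versions)}",
            )
        )
    return _sorted(findings)
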