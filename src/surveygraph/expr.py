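"""Expression language for conditional visibility (branching logic) and scores.

The grammar is C-like with standard precedence::

    unary (!, -)  >  * / %  >  + -  >  == != < <= > >=  >  &&  >  ||

plus aggregate calls ``sum, mean, sd, min, max, count`` and the predicates
``isMissing(x)`` and ``has(x, v)`` (multiselect membership).

Missing-value semantics
-----------------------
* arithmetic touching MISSING yields MISSING (poison),
* a comparison touching MISSING yields ``false``,
* a MISSING operand of ``&&``/``||``/``!`` behaves as ``false``,
* aggregates skip MISSING arguments; ``count`` counts the non-missing ones;
  ``sum/mean/min/max`` of zero non-missing arguments are MISSING,
* ``sd`` is the sample standard deviation (n-1 denominator) and is MISSING
  with fewer than 2 non-missing arguments,
* division (or modulo) by zero yields MISSING,
* an unbound variable evaluates to MISSING, never an exception.

Visibility expressions must evaluate to a boolean; numbers are not truthy.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Any, Optional, Union


class _Missing:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:  # guard against accidental truthiness
        raise TypeError("MISSING has no truth value")


MISSING = _Missing()


class ExpressionError(ValueError):
    """Syntax error; carries the character offset of the offending token."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class EvaluationError(ValueError):
    """Type error during evaluation, naming the offending node."""


class CycleDetected(ValueError):
    """Compute-rule cycle; carries the set of variables in the loop."""

    def __init__(self, variables: set[str]):
        super().__init__(f"compute-rule cycle involving {sorted(variables)}")
        self.variables = variables


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lit:
    value: Union[int, float, str, bool]


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Unary:
    op: str  # ! or -
    operand: "Node"


@dataclass(frozen=True)
class Binary:
    op: str
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Call:
    fn: str
    args: tuple["Node", ...]


Node = Union[Lit, Var, Unary, Binary, Call]

FUNCTIONS = frozenset({"sum", "mean", "sd", "min", "max", "count", "isMissing", "has"})

_PRECEDENCE = {
    "||": 1,
    "&&": 2,
    "==": 3, "!=": 3, "<": 3, "<=": 3, ">": 3, ">=": 3,
    "+": 4, "-": 4,
    "*": 5, "/": 5, "%": 5,
}
_UNARY_PRECEDENCE = 6


@dataclass
class Expression:
    """Parsed expression: source text, AST, and the set of referenced variables."""

    source: str
    ast: Node
    refs: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.refs = frozenset(_collect_refs(self.ast))


def _collect_refs(node: Node) -> set[str]:
    if isinstance(node, Var):
        return {node.name}
    if isinstance(node, Unary):
        return _collect_refs(node.operand)
    if isinstance(node, Binary):
        return _collect_refs(node.left) | _collect_refs(node.right)
    if isinstance(node, Call):
        out: set[str] = set()
        for a in node.args:
            out |= _collect_refs(a)
        return out
    return set()


# ---------------------------------------------------------------------------
# Tokenizer + Pratt parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<num>\d+\.\d+|\d+)
  | (?P<str>"(?:[^"\\]|\\.)*"|'(?:[^'\\]|\\.)*')
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op>&&|\|\||==|!=|<=|>=|[-+*/%<>!(),])
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ExpressionError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group(), pos))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val, off = self.peek()
        if val != value:
            raise ExpressionError(f"expected {value!r}, found {val or 'end of input'!r}", off)
        return self.advance()

    def parse(self) -> Node:
        node = self.parse_expr(0)
        kind, val, off = self.peek()
        if kind != "eof":
            raise ExpressionError(f"trailing tokens starting at {val!r}", off)
        return node

    def parse_expr(self, min_prec: int) -> Node:
        node = self.parse_prefix()
        while True:
            kind, val, off = self.peek()
            prec = _PRECEDENCE.get(val)
            if kind != "op" or prec is None or prec < min_prec:
                return node
            self.advance()
            right = self.parse_expr(prec + 1)  # left-associative
            node = Binary(val, node, right)

    def parse_prefix(self) -> Node:
        kind, val, off = self.advance()
        if kind == "num":
            return Lit(float(val) if "." in val else int(val))
        if kind == "str":
            body = val[1:-1]
            return Lit(re.sub(r"\\(.)", r"\1", body))
        if kind == "name":
            if val in ("true", "false"):
                return Lit(val == "true")
            if self.peek()[1] == "(":
                if val not in FUNCTIONS:
                    raise ExpressionError(f"unknown function {val!r}", off)
                self.advance()
                args: list[Node] = []
                if self.peek()[1] != ")":
                    args.append(self.parse_expr(0))
                    while self.peek()[1] == ",":
                        self.advance()
                        args.append(self.parse_expr(0))
                self.expect(")")
                return Call(val, tuple(args))
            return Var(val)
        if val == "(":
            node = self.parse_expr(0)
            self.expect(")")
            return node
        if val in ("!", "-"):
            return Unary(val, self.parse_expr(_UNARY_PRECEDENCE))
        raise ExpressionError(
            f"unexpected {val or 'end of input'!r}", off
        )


def parse_expression(text: str) -> Expression:
    """Parse source text into an :class:`Expression`; errors carry an offset."""
    if not text or not text.strip():
        raise ExpressionError("empty expression", 0)
    ast = _Parser(text).parse()
    return Expression(source=text, ast=ast)


# ---------------------------------------------------------------------------
# Serialization (minimal parentheses; parse∘serialize is a fixed point)
# ---------------------------------------------------------------------------

def serialize(node: Node) -> str:
    return _serialize(node, 0)


def _serialize(node: Node, parent_prec: int) -> str:
    if isinstance(node, Lit):
        if isinstance(node.value, bool):
            return "true" if node.value else "false"
        if isinstance(node.value, str):
            escaped = node.value.replace("\\", "\\\\").replace('"', '\\"')
            return f'"{escaped}"'
        if isinstance(node.value, float) and node.value.is_integer():
            return f"{node.value:.1f}"
        return repr(node.value)
    if isinstance(node, Var):
        return node.name
    if isinstance(node, Call):
        args = ", ".join(_serialize(a, 0) for a in node.args)
        return f"{node.fn}({args})"
    if isinstance(node, Unary):
        inner = _serialize(node.operand, _UNARY_PRECEDENCE)
        text = f"{node.op}{inner}"
        return f"({text})" if parent_prec > _UNARY_PRECEDENCE else text
    if isinstance(node, Binary):
        prec = _PRECEDENCE[node.op]
        left = _serialize(node.left, prec)
        right = _serialize(node.right, prec + 1)
        text = f"{left} {node.op} {right}"
        return f"({text})" if prec < parent_prec else text
    raise TypeError(f"not an AST node: {node!r}")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

Bindings = dict[str, Any]


def _is_number(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def _as_bool(v: Any, context: str) -> bool:
    if v is MISSING:
        return False
    if isinstance(v, bool):
        return v
    raise EvaluationError(f"{context}: expected boolean, got {v!r}")


def evaluate(expr: Union[Expression, Node], bindings: Bindings) -> Any:
    """Evaluate under the missing-value semantics documented in this module."""
    node = expr.ast if isinstance(expr, Expression) else expr
    return _eval(node, bindings)


def _eval(node: Node, b: Bindings) -> Any:
    if isinstance(node, Lit):
        return node.value
    if isinstance(node, Var):
        return b.get(node.name, MISSING)
    if isinstance(node, Unary):
        v = _eval(node.operand, b)
        if node.op == "!":
            return not _as_bool(v, "operand of !")
        if v is MISSING:
            return MISSING
        if not _is_number(v):
            raise EvaluationError(f"operand of unary - must be numeric, got {v!r}")
        return -v
    if isinstance(node, Binary):
        return _eval_binary(node, b)
    if isinstance(node, Call):
        return _eval_call(node, b)
    raise TypeError(f"not an AST node: {node!r}")


def _eval_binary(node: Binary, b: Bindings) -> Any:
    op = node.op
    if op == "&&":
        if not _as_bool(_eval(node.left, b), "left of &&"):
            return False
        return _as_bool(_eval(node.right, b), "right of &&")
    if op == "||":
        if _as_bool(_eval(node.left, b), "left of ||"):
            return True
        return _as_bool(_eval(node.right, b), "right of ||")

    left = _eval(node.left, b)
    right = _eval(node.right, b)

    if op in ("+", "-", "*", "/", "%"):
        if left is MISSING or right is MISSING:
            return MISSING
        if not (_is_number(left) and _is_number(right)):
            raise EvaluationError(f"arithmetic {op!r} requires numbers, got {left!r}, {right!r}")
        if op in ("/", "%") and right == 0:
            return MISSING
        result = {
            "+": lambda: left + right,
            "-": lambda: left - right,
            "*": lambda: left * right,
            "/": lambda: left / right,
            "%": lambda: left % right,
        }[op]()
        return result

    # comparisons
    if left is MISSING or right is MISSING:
        return False
    if op in ("==", "!="):
        equal = _values_equal(left, right)
        return equal if op == "==" else not equal
    if _is_number(left) and _is_number(right):
        pass
    elif isinstance(left, str) and isinstance(right, str):
        pass
    else:
        raise EvaluationError(f"cannot order {left!r} and {right!r} with {op!r}")
    return {"<": left < right, "<=": left <= right, ">": left > right, ">=": left >= right}[op]


def _values_equal(a: Any, b: Any) -> bool:
    if _is_number(a) and _is_number(b):
        return float(a) == float(b)
    return type(a) is type(b) and a == b


def _eval_call(node: Call, b: Bindings) -> Any:
    fn = node.fn
    if fn == "isMissing":
        if len(node.args) != 1:
            raise EvaluationError("isMissing takes exactly one argument")
        return _eval(node.args[0], b) is MISSING
    if fn == "has":
        if len(node.args) != 2:
            raise EvaluationError("has takes exactly two arguments")
        coll = _eval(node.args[0], b)
        needle = _eval(node.args[1], b)
        if coll is MISSING or needle is MISSING:
            return False
        if not isinstance(coll, (list, tuple)):
            raise EvaluationError(f"has() requires a multiselect value, got {coll!r}")
        return any(str(v) == str(needle) for v in coll)

    values = [_eval(a, b) for a in node.args]
    present = [v for v in values if v is not MISSING]
    for v in present:
        if not _is_number(v):
            raise EvaluationError(f"{fn}() requires numeric arguments, got {v!r}")
    if fn == "count":
        return len(present)
    if not present:
        return MISSING
    if fn == "sum":
        return float(sum(present))
    if fn == "mean":
        return float(sum(present)) / len(present)
    if fn == "min":
        return float(min(present))
    if fn == "max":
        return float(max(present))
    if fn == "sd":
        if len(present) < 2:
            return MISSING
        m = sum(present) / len(present)
        var = sum((x - m) ** 2 for x in present) / (len(present) - 1)
        return math.sqrt(var)
    raise EvaluationError(f"unknown function {fn!r}")  # unreachable after parse


# ---------------------------------------------------------------------------
# Activity-level operations
# ---------------------------------------------------------------------------

def visible_set(activity, bindings: Bindings) -> list[str]:
    """Ordered variable names of visible items.

    An item is visible iff it has no visibility expression or its expression
    evaluates to true under ``bindings``.
    """
    out = []
    for ref in activity.item_order:
        if ref.visibility is None:
            out.append(ref.variable_name)
            continue
        value = evaluate(parse_expression(ref.visibility), bindings)
        if _as_bool(value, f"visibility of {ref.variable_name!r}"):
            out.append(ref.variable_name)
    return out


def compute_scores(activity, bindings: Bindings) -> Bindings:
    """Evaluate compute rules in dependency order; returns extended bindings.

    Rules may reference other rules' targets; they are resolved in topological
    order so chained scores work. A genuine cycle raises :class:`CycleDetected`.
    """
    rules = {r.target: parse_expression(r.expression) for r in activity.compute_rules}
    ts = TopologicalSorter(
        {target: {d for d in expr.refs if d in rules} for target, expr in rules.items()}
    )
    try:
        order = list(ts.static_order())
    except CycleError as exc:
        cyclic = {v for v in exc.args[1] if v in rules}
        raise CycleDetected(cyclic) from exc
    extended = dict(bindings)
    for target in order:
        extended[target] = evaluate(rules[target], extended)
    return extended
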