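"""Independent brute-force oracle for the expression engine.

Translates expression source to Python syntax and evaluates it by walking
Python's own AST (so operator precedence comes from CPython's parser, not
from the package), applying the documented missing-value semantics directly:
arithmetic poisons, comparisons are false, aggregates skip, sd uses n-1,
division by zero is missing.
"""

from __future__ import annotations

import ast
import math
import re


class Missing:
    def __repr__(self):
        return "ORACLE_MISSING"


OM = Missing()


def _to_python(source: str) -> str:
    text = re.sub(r"&&", " and ", source)
    text = re.sub(r"\|\|", " or ", text)
    text = re.sub(r"!(?!=)", " not ", text)
    text = re.sub(r"\btrue\b", "True", text)
    text = re.sub(r"\bfalse\b", "False", text)
    return text.strip()


def oracle_eval(source: str, bindings: dict) -> object:
    tree = ast.parse(_to_python(source), mode="eval")
    return _walk(tree.body, bindings)


def _num(v):
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def _walk(node: ast.AST, b: dict):
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.Name):
        v = b.get(node.id, OM)
        return OM if v is OM else v
    if isinstance(node, ast.UnaryOp):
        v = _walk(node.operand, b)
        if isinstance(node.op, ast.Not):
            return not (v is not OM and v is True)
        if isinstance(node.op, ast.USub):
            return OM if v is OM else -v
        raise NotImplementedError(node.op)
    if isinstance(node, ast.BoolOp):
        values = [_walk(v, b) for v in node.values]
        coerced = [(v is not OM and v is True) for v in values]
        return all(coerced) if isinstance(node.op, ast.And) else any(coerced)
    if isinstance(node, ast.Compare):
        assert len(node.ops) == 1, "chained comparisons not in the grammar"
        left = _walk(node.left, b)
        right = _walk(node.comparators[0], b)
        if left is OM or right is OM:
            return False
        op = node.ops[0]
        if isinstance(op, ast.Eq):
            return _eq(left, right)
        if isinstance(op, ast.NotEq):
            return not _eq(left, right)
        return {
            ast.Lt: lambda: left < right,
            ast.LtE: lambda: left <= right,
            ast.Gt: lambda: left > right,
            ast.GtE: lambda: left >= right,
        }[type(op)]()
    if isinstance(node, ast.BinOp):
        left = _walk(node.left, b)
        right = _walk(node.right, b)
        if left is OM or right is OM:
            return OM
        if isinstance(node.op, (ast.Div, ast.Mod)) and right == 0:
            return OM
        return {
            ast.Add: lambda: left + right,
            ast.Sub: lambda: left - right,
            ast.Mult: lambda: left * right,
            ast.Div: lambda: left / right,
            ast.Mod: lambda: left % right,
        }[type(node.op)]()
    if isinstance(node, ast.Call):
        fn = node.func.id
        args = [_walk(a, b) for a in node.args]
        if fn == "isMissing":
            return args[0] is OM
        if fn == "has":
            coll, needle = args
            if coll is OM or needle is OM:
                return False
            return any(str(v) == str(needle) for v in coll)
        present = [a for a in args if a is not OM]
        if fn == "count":
            return len(present)
        if not present:
            return OM
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
                return OM
            m = sum(present) / len(present)
            return math.sqrt(sum((x - m) ** 2 for x in present) / (len(present) - 1))
        raise NotImplementedError(fn)
    raise NotImplementedError(ast.dump(node))


def _eq(a, b):
    if _num(a) and _num(b):
        return float(a) == float(b)
    return type(a) is type(b) and a == b


def oracle_visible_set(activity, bindings: dict) -> list[str]:
    out = []
    for ref in activity.item_order:
        if ref.visibility is None:
            out.append(ref.variable_name)
        elif oracle_eval(ref.visibility, bindings) is True:
            out.append(ref.variable_name)
    return out


def oracle_compute_scores(activity, bindings: dict) -> dict:
    """Fixed-point iteration instead of a topological sort: after n passes
    over n acyclic rules every target has its final value."""
    env = dict(bindings)
    rules = [(r.target, r.expression) for r in activity.compute_rules]
    for _ in range(max(1, len(rules))):
        for target, expression in rules:
            env[target] = oracle_eval(expression, env)
    return env
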