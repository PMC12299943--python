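"""Expression engine: grammar, missing-value semantics, activity operations."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from surveygraph import (
    MISSING,
    CycleDetected,
    EvaluationError,
    ExpressionError,
    ComputeRule,
    ItemRef,
    compute_scores,
    evaluate,
    parse_expression,
    serialize,
    visible_set,
)
from surveygraph.expr import Binary, Call, Lit, Unary, Var

from _oracle import OM, oracle_eval
from conftest import make_activity, make_item


class TestParsing:
    def test_precedence_mul_over_add(self):
        expr = parse_expression("a + b * 2")
        assert expr.ast == Binary("+", Var("a"), Binary("*", Var("b"), Lit(2)))
        assert expr.refs == {"a", "b"}

    def test_aggregate_call_arity(self):
        expr = parse_expression("mean(q1, q2, q3, q4, q5)")
        assert isinstance(expr.ast, Call)
        assert expr.ast.fn == "mean"
        assert len(expr.ast.args) == 5
        assert expr.refs == {"q1", "q2", "q3", "q4", "q5"}

    @pytest.mark.parametrize(
        "source, offset",
        [("q1 +", 4), ("(a + b", 6), ("a b", 2)],
    )
    def test_syntax_error_offsets(self, source, offset):
        with pytest.raises(ExpressionError) as exc:
            parse_expression(source)
        assert exc.value.offset == offset

    def test_unknown_function_rejected(self):
        with pytest.raises(ExpressionError):
            parse_expression("median(a, b)")

    def test_empty_expression_rejected(self):
        with pytest.raises(ExpressionError):
            parse_expression("   ")

    @pytest.mark.parametrize(
        "source",
        [
            "a + b * 2",
            "(a + b) * 2",
            "!(x == 1) && y >= 2 || z < 0",
            'severity == "moderate"',
            "-a - -b",
            "mean(q1, q2) > 1.5",
            "a - (b - c)",
            "isMissing(x) || has(meds, \"2\")",
        ],
    )
    def test_serialize_parse_fixed_point(self, source):
        once = serialize(parse_expression(source).ast)
        assert serialize(parse_expression(once).ast) == once
        assert parse_expression(once).ast == parse_expression(source).ast


_leaf = st.one_of(
    st.integers(min_value=0, max_value=9).map(Lit),
    st.sampled_from(["a", "b", "q1", "q2"]).map(Var),
    st.booleans().map(Lit),
)


def _trees(children):
    ops = st.sampled_from(list("+-*/%") + ["==", "!=", "<", "<=", ">", ">=", "&&", "||"])
    return st.one_of(
        st.tuples(ops, children, children).map(lambda t: Binary(*t)),
        st.tuples(st.sampled_from(["!", "-"]), children).map(lambda t: Unary(*t)),
        st.tuples(
            st.sampled_from(["sum", "mean", "sd", "min", "max", "count"]),
            st.lists(children, min_size=1, max_size=4).map(tuple),
        ).map(lambda t: Call(*t)),
    )


@settings(max_examples=200, derandomize=True)
@given(st.recursive(_leaf, _trees, max_leaves=12))
def test_serialize_round_trips_random_asts(node):
    """parse(serialize(ast)) reproduces the tree for arbitrary ASTs."""
    assert parse_expression(serialize(node)).ast == node


class TestEvaluation:
    def test_mean_of_five(self):
        expr = parse_expression("mean(q1, q2, q3, q4, q5)")
        values = dict(zip("q1 q2 q3 q4 q5".split(), [1, 2, 3, 0, 4]))
        assert evaluate(expr, values) == 2.0

    def test_sd_of_constant_sample_is_zero(self):
        assert evaluate(parse_expression("sd(a, b, c)"), {"a": 2, "b": 2, "c": 2}) == 0.0

    def test_sample_sd_uses_n_minus_1(self):
        got = evaluate(parse_expression("sd(a, b, c)"), {"a": 1, "b": 2, "c": 3})
        assert got == pytest.approx(1.0)

    def test_comparison_with_unbound_is_false(self):
        assert evaluate(parse_expression("q1 >= 2"), {}) is False

    def test_arithmetic_poisons_on_missing(self):
        assert evaluate(parse_expression("q1 + 1"), {}) is MISSING

    def test_aggregates_skip_missing(self):
        b = {"a": 1, "c": 3}
        assert evaluate(parse_expression("mean(a, b, c)"), b) == 2.0
        assert evaluate(parse_expression("count(a, b, c)"), b) == 2
        assert evaluate(parse_expression("sum(a, b, c)"), b) == 4.0

    def test_all_missing_aggregate_is_missing(self):
        assert evaluate(parse_expression("mean(a, b)"), {}) is MISSING
        assert evaluate(parse_expression("sd(a, b, c)"), {"a": 1}) is MISSING
        assert evaluate(parse_expression("count(a, b)"), {}) == 0

    def test_division_by_zero_is_missing(self):
        assert evaluate(parse_expression("a / b"), {"a": 1, "b": 0}) is MISSING
        assert evaluate(parse_expression("a % b"), {"a": 1, "b": 0}) is MISSING

    def test_is_missing_and_has(self):
        assert evaluate(parse_expression("isMissing(x)"), {}) is True
        assert evaluate(parse_expression("isMissing(x)"), {"x": 1}) is False
        assert evaluate(parse_expression('has(meds, "2")'), {"meds": [1, 2]}) is True
        assert evaluate(parse_expression('has(meds, "3")'), {"meds": [1, 2]}) is False
        assert evaluate(parse_expression('has(meds, "3")'), {}) is False

    def test_string_in_arithmetic_is_an_error(self):
        with pytest.raises(EvaluationError):
            evaluate(parse_expression("a + 1"), {"a": "two"})

    def test_numbers_are_not_truthy_in_boolean_context(self):
        with pytest.raises(EvaluationError):
            evaluate(parse_expression("a && b"), {"a": 1, "b": 2})

    def test_string_equality(self):
        b = {"severity": "moderate"}
        assert evaluate(parse_expression('severity == "moderate"'), b) is True
        assert evaluate(parse_expression('severity != "mild"'), b) is True


class TestAggregateFormulas:
    def test_agree_with_two_pass_formulas(self):
        """mean/sum/sd match direct two-pass computation within 1e-12."""
        import numpy as np

        rng = random.Random(42)
        worst = 0.0
        for _ in range(1000):
            n = rng.randint(2, 12)
            xs = [rng.uniform(-50, 50) for _ in range(n)]
            names = [f"v{i}" for i in range(n)]
            b = dict(zip(names, xs))
            arglist = ", ".join(names)
            arr = np.array(xs)
            worst = max(
                worst,
                abs(evaluate(parse_expression(f"sum({arglist})"), b) - arr.sum()),
                abs(evaluate(parse_expression(f"mean({arglist})"), b) - arr.mean()),
                abs(evaluate(parse_expression(f"sd({arglist})"), b) - arr.std(ddof=1)),
            )
        assert worst < 1e-12


class TestVisibleSet:
    def test_no_expressions_yields_all_in_order(self):
        act = make_activity("a", [ItemRef(variable_name=v, item=make_item(v)) for v in ("x", "y", "z")])
        assert visible_set(act, {}) == ["x", "y", "z"]

    def test_gated_follow_up_hidden(self):
        act = make_activity(
            "a",
            [
                ItemRef(variable_name="g", item=make_item("g")),
                ItemRef(variable_name="f", item=make_item("f"), visibility="g == 1"),
            ],
        )
        assert visible_set(act, {"g": 0}) == ["g"]
        assert visible_set(act, {"g": 1}) == ["g", "f"]

    def test_score_threshold_gate(self):
        """Adaptive triggering: follow-up appears when a score exceeds a threshold."""
        expr = parse_expression("anxiety_score > 2")
        assert evaluate(expr, {"anxiety_score": 3}) is True
        assert evaluate(expr, {"anxiety_score": 2}) is False


class TestComputeScores:
    def test_subscale_mean_of_first_five(self):
        act = make_activity(
            "a",
            [ItemRef(variable_name=f"q{i}", item=make_item(f"q{i}")) for i in range(1, 6)],
            [ComputeRule(target="anxiety", expression="mean(q1, q2, q3, q4, q5)")],
        )
        out = compute_scores(act, {f"q{i}": 2 for i in range(1, 6)})
        assert out["anxiety"] == 2.0

    def test_chained_rules_resolve_in_dependency_order(self):
        act = make_activity(
            "a",
            [ItemRef(variable_name="a", item=make_item("a"))],
            [ComputeRule(target="c", expression="b * 2"), ComputeRule(target="b", expression="a + 1")],
        )
        assert compute_scores(act, {"a": 1})["c"] == 4.0

    def test_cycle_raises_naming_the_loop(self):
        act = make_activity(
            "act",
            [ItemRef(variable_name="x", item=make_item("x"))],
            [ComputeRule(target="a", expression="b"), ComputeRule(target="b", expression="a")],
        )
        with pytest.raises(CycleDetected) as exc:
            compute_scores(act, {"x": 1})
        assert exc.value.variables == {"a", "b"}

    def test_all_missing_inputs_yield_missing(self):
        act = make_activity(
            "a",
            [ItemRef(variable_name="q1", item=make_item("q1"))],
            [ComputeRule(target="s", expression="mean(q1)")],
        )
        assert compute_scores(act, {})["s"] is MISSING


@settings(max_examples=300, derandomize=True)
@given(
    source=st.sampled_from(
        [
            "a + b * 2 - c / 2",
            "a >= 1 && b < 2 || c == 0",
            "mean(a, b, c) > 1",
            "sd(a, b, c) + sum(a, b)",
            "!(a == b) || isMissing(c)",
            "min(a, b) <= max(b, c)",
            "a % 2 == 0 && !(b != 1)",
        ]
    ),
    values=st.lists(st.one_of(st.integers(0, 3), st.none()), min_size=3, max_size=3),
)
def test_evaluator_matches_independent_oracle(source, values):
    """The evaluator agrees with a Python-AST-based oracle on random bindings."""
    bindings = {n: v for n, v in zip("abc", values) if v is not None}
    try:
        got = evaluate(parse_expression(source), bindings)
    except EvaluationError:
        pytest.skip("type error path")
    want = oracle_eval(source, bindings)
    if want is OM:
        assert got is MISSING
    elif isinstance(want, float):
        assert got == pytest.approx(want, abs=1e-12)
    else:
        assert got == want
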