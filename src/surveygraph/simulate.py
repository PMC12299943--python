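"""Synthetic protocol generator and respondent simulator.

Everything downstream (validation, scoring, converters, diffing) is testable
without external data: :func:`generate_protocol` builds a valid protocol with
a realistic mix of input types, :func:`mutate_protocol` applies exactly one
semantic change of a requested class (the diff test harness), and
:func:`simulate_responses` walks respondents through the branching logic.

Default study conditions: two activities of six items each — a run of
5-point Likert radios (codes 0–4, "Not at all" … "Extremely"), one bounded
integer item (18–99), one three-choice multiselect and one free-text item —
with a mean-of-first-five subscale score per activity, 30% of eligible items
gated on an earlier answer, a declined/skipped code of -9 used at rate 0.1,
and 100 respondents. Responses are sampled uniformly; no psychometric
structure is modelled.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass

from .expr import compute_scores, evaluate, parse_expression, visible_set, MISSING
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

MISSING_CODE = -9

LIKERT_LABELS = ["Not at all", "A little", "Moderately", "Quite a bit", "Extremely"]

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


class MutationError(ValueError):
    """The requested change class is inapplicable to this graph."""


@dataclass
class SimConfig:
    seed: int = 0
    n_activities: int = 2
    items_per_activity: int = 6
    branching_fraction: float = 0.3
    scoring: bool = True
    score_k: int = 5
    n_respondents: int = 100
    missingness_rate: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.branching_fraction <= 1.0):
            raise ValueError("branching_fraction must be in [0, 1]")
        if not (0.0 <= self.missingness_rate <= 1.0):
            raise ValueError("missingness_rate must be in [0, 1]")
        if min(self.n_activities, self.items_per_activity, self.n_respondents) < 1:
            raise ValueError("counts must be positive")


# ---------------------------------------------------------------------------
# Protocol generation
# ---------------------------------------------------------------------------

def _likert_options() -> ResponseOptions:
    return ResponseOptions(
        value_type="integer",
        choices=[Choice(i, LanguageMap.of(lbl)) for i, lbl in enumerate(LIKERT_LABELS)],
        multiple_choice=False,
        missing_codes=[MISSING_CODE],
    )


QUESTION_STEMS = [
    "Feeling nervous or on edge",
    "Not being able to stop worrying",
    "Feeling down or hopeless",
    "Little interest or pleasure in doing things",
    "Trouble relaxing",
    "Feeling tired or having little energy",
    "Trouble concentrating",
    "Feeling easily annoyed or irritable",
]


def _make_item(kind: str, var: str, rng: random.Random) -> Item:
    if kind == "radio":
        stem = rng.choice(QUESTION_STEMS)
        return Item(
            name=var,
            question=LanguageMap.of(f"{stem} ({var})"),
            input_type="radio",
            response_options=_likert_options(),
        )
    if kind == "integer":
        return Item(
            name=var,
            question=LanguageMap.of(f"What is your age? ({var})"),
            input_type="integer",
            response_options=ResponseOptions(
                value_type="integer", min_value=18, max_value=99, missing_codes=[MISSING_CODE]
            ),
        )
    if kind == "multiselect":
        return Item(
            name=var,
            question=LanguageMap.of(f"Select all that apply ({var})"),
            input_type="multiselect",
            response_options=ResponseOptions(
                value_type="integer",
                choices=[
                    Choice(1, LanguageMap.of("Sleep problems")),
                    Choice(2, LanguageMap.of("Appetite changes")),
                    Choice(3, LanguageMap.of("Social withdrawal")),
                ],
                multiple_choice=True,
            ),
        )
    if kind == "text":
        return Item(
            name=var,
            question=LanguageMap.of(f"Anything else you would like to add? ({var})"),
            input_type="text",
            response_options=ResponseOptions(value_type="string"),
        )
    raise ValueError(kind)


def generate_protocol(config: SimConfig) -> Protocol:
    """Generate a valid protocol graph; branching only references earlier
    items, so a single in-order pass evaluates all visibility gates."""
    rng = random.Random(config.seed)
    n_items = config.items_per_activity

    activity_refs = []
    for a in range(config.n_activities):
        name = f"act{a + 1}"
        # kinds: leading run of radios (scorable), then one each of the others
        kinds = ["radio"] * n_items
        if n_items >= 4:
            kinds[-1] = "text"
            kinds[-2] = "multiselect"
            kinds[-3] = "integer"
        item_refs = []
        branch_candidates = []  # earlier vars usable in comparisons
        forced_branch = None
        if config.branching_fraction > 0 and n_items >= 2:
            forced_branch = rng.randrange(1, n_items)
        for i, kind in enumerate(kinds):
            var = f"{name}_q{i + 1}"
            visibility = None
            eligible = branch_candidates and kind != "static_display"
            if eligible and (
                rng.random() < config.branching_fraction or i == forced_branch
            ):
                gate = rng.choice(branch_candidates)
                threshold = rng.randint(1, 3)
                visibility = f"{gate} >= {threshold}"
            item_refs.append(
                ItemRef(
                    variable_name=var,
                    item=_make_item(kind, var, rng),
                    visibility=visibility,
                    required=kind == "radio",
                )
            )
            if kind in ("radio", "integer"):
                branch_candidates.append(var)

        rules = []
        if config.scoring:
            k = min(config.score_k, sum(1 for kk in kinds if kk == "radio"))
            if k >= 1:
                args = ", ".join(f"{name}_q{i + 1}" for i in range(k))
                rules.append(ComputeRule(target=f"{name}_score", expression=f"mean({args})"))

        activity = Activity(
            name=name,
            pref_label=LanguageMap.of(f"Assessment {a + 1}"),
            item_order=item_refs,
            compute_rules=rules,
        )
        visibility = None
        if a > 0 and config.scoring:
            # adaptive design: later assessments trigger on the previous score
            visibility = f"act{a}_score >= 0"
        activity_refs.append(
            ActivityRef(name=name, activity=activity, visibility=visibility, required=True)
        )

    protocol = Protocol(
        name=LanguageMap.of(f"Simulated study {config.seed}"),
        description=LanguageMap.of("Synthetic protocol for testing"),
        activity_order=activity_refs,
        base_iri=f"https://example.org/surveygraph/sim{config.seed}",
    )
    pin_versions(protocol)
    return protocol


# ---------------------------------------------------------------------------
# Single-class mutations (diff test harness)
# ---------------------------------------------------------------------------

def _referenced_vars(protocol: Protocol) -> set[str]:
    refs: set[str] = set()
    for aref in protocol.activity_order:
        if aref.visibility:
            refs |= parse_expression(aref.visibility).refs
        for iref in aref.activity.item_order:
            if iref.visibility:
                refs |= parse_expression(iref.visibility).refs
        for rule in aref.activity.compute_rules:
            refs |= parse_expression(rule.expression).refs
    return refs


def mutate_protocol(protocol: Protocol, change_class: str, seed: int = 0) -> Protocol:
    """Return a deep copy with exactly one semantic change of the given class."""
    if change_class not in CHANGE_CLASSES:
        raise MutationError(f"unknown change class {change_class!r}")
    rng = random.Random(seed)
    mutated = copy.deepcopy(protocol)
    acts = [aref.activity for aref in mutated.activity_order]

    if change_class == "metadata":
        mutated.license = mutated.license + "-mutated" if mutated.license else "CC0-1.0"
    elif change_class == "wording":
        candidates = [iref for a in acts for iref in a.item_order]
        if not candidates:
            raise MutationError("no items to reword")
        iref = rng.choice(candidates)
        lang = mutated.default_language
        text = iref.item.question.get(lang, lang)
        iref.item.question.entries[lang] = text + "?"
    elif change_class == "response_scale":
        candidates = [
            iref
            for a in acts
            for iref in a.item_order
            if iref.item.input_type == "radio" and iref.item.response_options is not None
        ]
        if not candidates:
            raise MutationError("no choice item to rescale")
        iref = rng.choice(candidates)
        opts = iref.item.response_options
        next_code = max(int(c.value) for c in opts.choices) + 1
        opts.choices.append(Choice(next_code, LanguageMap.of("Very severely")))
        opts.choices.append(Choice(next_code + 1, LanguageMap.of("Extremely severely")))
    elif change_class == "logic":
        candidates = [
            iref for a in acts for iref in a.item_order if iref.visibility is not None
        ]
        if not candidates:
            raise MutationError("no visibility expression to change")
        iref = rng.choice(candidates)
        expr = parse_expression(iref.visibility)
        from .expr import Binary, Lit, serialize

        node = expr.ast
        if isinstance(node, Binary) and isinstance(node.right, Lit):
            node = Binary(node.op, node.left, Lit(node.right.value + 1))
            iref.visibility = serialize(node)
        else:
            iref.visibility = f"({iref.visibility}) && true"
    elif change_class == "scoring":
        candidates = [a for a in acts if a.compute_rules]
        if not candidates:
            raise MutationError("no compute rule to change")
        act = rng.choice(candidates)
        rule = rng.choice(act.compute_rules)
        rule.expression = f"({rule.expression}) * 2"
    elif change_class == "item_added":
        act = rng.choice(acts)
        var = f"{act.name}_extra"
        if act.get_item_ref(var) is not None:
            raise MutationError("extra item already present")
        act.item_order.append(
            ItemRef(variable_name=var, item=_make_item("radio", var, rng))
        )
    elif change_class == "item_removed":
        # only unreferenced variables are removable, so the graph stays valid
        protected = _referenced_vars(mutated)
        candidates = [
            (a, iref)
            for a in acts
            for iref in a.item_order
            if iref.variable_name not in protected
        ]
        if not candidates:
            raise MutationError("no removable item")
        act, iref = rng.choice(candidates)
        act.item_order.remove(iref)
    elif change_class == "reordered":
        candidates = [a for a in acts if len(a.item_order) >= 2]
        if not candidates:
            raise MutationError("no activity with two items to reorder")
        act = rng.choice(candidates)
        i = rng.randrange(len(act.item_order) - 1)
        act.item_order[i], act.item_order[i + 1] = act.item_order[i + 1], act.item_order[i]

    pin_versions(mutated)
    return mutated


# ---------------------------------------------------------------------------
# Respondent simulation
# ---------------------------------------------------------------------------

def _sample_value(item: Item, rng: random.Random):
    opts = item.response_options
    if opts is None:
        return None
    if opts.multiple_choice:
        values = opts.choice_values()
        k = rng.randint(1, len(values))
        return sorted(rng.sample(values, k), key=str)
    if opts.choices:
        return rng.choice(opts.choice_values())
    if opts.value_type == "integer":
        lo = int(opts.min_value) if opts.min_value is not None else 0
        hi = int(opts.max_value) if opts.max_value is not None else 10
        return rng.randint(lo, hi)
    if opts.value_type == "decimal":
        lo = opts.min_value if opts.min_value is not None else 0.0
        hi = opts.max_value if opts.max_value is not None else 1.0
        return round(rng.uniform(lo, hi), 3)
    return rng.choice(["fine", "okay", "no comment", "n/a", "better than last week"])


def simulate_responses(protocol: Protocol, config: SimConfig) -> list[ResponseRecord]:
    """Answer items respondent by respondent, honouring visibility gates.

    An item gets a value iff it is visible given the answers so far; with
    probability ``missingness_rate`` a declared missing code is recorded
    (and the variable is bound as missing for later branching). Computed
    scores are evaluated for gating but never stored as records.
    """
    rng = random.Random(config.seed * 7919 + 17)
    records: list[ResponseRecord] = []
    width = max(3, len(str(config.n_respondents)))

    for r in range(config.n_respondents):
        respondent = f"p{r + 1:0{width}d}"
        bindings: dict = {}
        minute = 0
        for aref in protocol.activity_order:
            if aref.visibility is not None:
                shown = evaluate(parse_expression(aref.visibility), bindings)
                if shown is not True:
                    continue
            act = aref.activity
            for iref in act.item_order:
                if iref.variable_name not in visible_set(act, bindings):
                    continue
                if iref.item.input_type == "static_display":
                    continue
                opts = iref.item.response_options
                codes = opts.missing_codes if opts else []
                if codes and rng.random() < config.missingness_rate:
                    value = codes[0]
                    bindings[iref.variable_name] = MISSING
                else:
                    value = _sample_value(iref.item, rng)
                    bindings[iref.variable_name] = value
                minute += 1
                records.append(
                    ResponseRecord(
                        respondent=respondent,
                        protocol_id=protocol.id,
                        activity_id=act.id,
                        item_id=iref.item.id,
                        variable_name=iref.variable_name,
                        value=value,
                        answered_at=f"2025-01-01T09:{r % 50:02d}:{minute % 60:02d}Z",
                    )
                )
            bindings = compute_scores(act, bindings)
    return records
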