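"""Starter protocol scaffold for the ``new`` command.

The generated tree is a minimal but complete worked example: a screening
activity with an age field (bounded 18–99), a controlled-vocabulary severity
item, a five-question Likert block with a computed anxiety subscore (mean of
the five), and a follow-up question that appears adaptively when the score
exceeds a threshold.
"""

from __future__ import annotations

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
)
from .storage import pin_versions

ANXIETY_QUESTIONS = [
    "Feeling nervous, anxious, or on edge",
    "Not being able to stop or control worrying",
    "Worrying too much about different things",
    "Trouble relaxing",
    "Being so restless that it is hard to sit still",
]

LIKERT_4 = [(0, "Not at all"), (1, "Several days"), (2, "More than half the days"), (3, "Nearly every day")]


def new_protocol(name: str = "starter") -> Protocol:
    items = [
        ItemRef(
            variable_name="age",
            item=Item(
                name="age",
                question=LanguageMap.of("What is your age in years?"),
                input_type="integer",
                response_options=ResponseOptions(
                    value_type="integer", min_value=18, max_value=99, missing_codes=[-9]
                ),
            ),
            required=True,
        ),
        ItemRef(
            variable_name="severity",
            item=Item(
                name="severity",
                question=LanguageMap.of("How would you rate your current symptom severity?"),
                input_type="select",
                response_options=ResponseOptions(
                    value_type="code",
                    choices=[
                        Choice("mild", LanguageMap.of("Mild")),
                        Choice("moderate", LanguageMap.of("Moderate")),
                        Choice("severe", LanguageMap.of("Severe")),
                    ],
                ),
            ),
            required=True,
        ),
    ]
    for i, stem in enumerate(ANXIETY_QUESTIONS, start=1):
        items.append(
            ItemRef(
                variable_name=f"q{i}",
                item=Item(
                    name=f"q{i}",
                    question=LanguageMap.of(stem),
                    input_type="radio",
                    response_options=ResponseOptions(
                        value_type="integer",
                        choices=[Choice(v, LanguageMap.of(lbl)) for v, lbl in LIKERT_4],
                        missing_codes=[-9],
                    ),
                ),
                required=True,
            )
        )
    items.append(
        ItemRef(
            variable_name="followup",
            item=Item(
                name="followup",
                question=LanguageMap.of(
                    "Your answers suggest elevated anxiety. Would you like to be contacted?"
                ),
                input_type="radio",
                response_options=ResponseOptions(
                    value_type="integer",
                    choices=[Choice(1, LanguageMap.of("Yes")), Choice(0, LanguageMap.of("No"))],
                ),
            ),
            visibility="anxiety_score > 2",
        )
    )
    activity = Activity(
        name="screening",
        pref_label=LanguageMap.of("Screening questionnaire"),
        item_order=items,
        compute_rules=[
            ComputeRule(target="anxiety_score", expression="mean(q1, q2, q3, q4, q5)")
        ],
    )
    protocol = Protocol(
        name=LanguageMap.of(name),
        description=LanguageMap.of("Starter protocol scaffold — edit the documents under activities/"),
        activity_order=[ActivityRef(name="screening", activity=activity, required=True)],
        base_iri=f"https://example.org/surveygraph/{name}",
    )
    pin_versions(protocol)
    return protocol
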