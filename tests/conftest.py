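import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helper

from surveygraph import (
    Activity,
    ActivityRef,
    Choice,
    ComputeRule,
    Item,
    ItemRef,
    LanguageMap,
    Protocol,
    ResponseOptions,
    SimConfig,
    generate_protocol,
    pin_versions,
    simulate_responses,
)


def likert(n: int = 4) -> ResponseOptions:
    labels = ["Not at all", "Several days", "More than half the days", "Nearly every day",
              "Always", "Constantly", "Beyond measure"]
    return ResponseOptions(
        value_type="integer",
        choices=[Choice(i, LanguageMap.of(labels[i])) for i in range(n)],
    )


def make_item(var: str, input_type: str = "radio", options: ResponseOptions | None = "default",
              question: str | None = None) -> Item:
    if options == "default":
        options = likert()
    return Item(
        name=var,
        question=LanguageMap.of(question or f"Question {var}"),
        input_type=input_type,
        response_options=options,
    )


def make_activity(name: str, refs: list[ItemRef], rules: list[ComputeRule] = ()) -> Activity:
    return Activity(
        name=name,
        pref_label=LanguageMap.of(name),
        item_order=refs,
        compute_rules=list(rules),
    )


def make_protocol(activities: list[Activity], name: str = "fixture") -> Protocol:
    protocol = Protocol(
        name=LanguageMap.of(name),
        description=LanguageMap.of("test fixture"),
        activity_order=[ActivityRef(name=a.name, activity=a, required=True) for a in activities],
        base_iri=f"https://example.org/surveygraph/{name}",
    )
    pin_versions(protocol)
    return protocol


def small_random_activity(rng: random.Random, n_items: int = 6, n_values: int = 3) -> Activity:
    """Activity with <= n_items items over <= n_values codes, random branching
    on earlier items and a couple of compute rules — for exhaustive checks."""
    refs = []
    for i in range(1, n_items + 1):
        var = f"q{i}"
        visibility = None
        if i > 1 and rng.random() < 0.5:
            gate = f"q{rng.randint(1, i - 1)}"
            op = rng.choice([">=", "==", "<", "!=", ">"])
            visibility = f"{gate} {op} {rng.randint(0, n_values - 1)}"
            if rng.random() < 0.3:
                other = f"q{rng.randint(1, i - 1)}"
                joiner = rng.choice(["&&", "||"])
                visibility = f"{visibility} {joiner} {other} <= {rng.randint(0, n_values - 1)}"
        refs.append(ItemRef(variable_name=var, item=make_item(var, options=likert(n_values)),
                            visibility=visibility))
    all_vars = [r.variable_name for r in refs]
    k = rng.randint(2, len(all_vars))
    fn = rng.choice(["mean", "sum", "sd", "min", "max", "count"])
    rules = [ComputeRule(target="score", expression=f"{fn}({', '.join(all_vars[:k])})")]
    if rng.random() < 0.5:
        rules.append(ComputeRule(target="flag", expression="score + 1"))
    return make_activity("small", refs, rules)


@pytest.fixture
def sim_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture
def sim_protocol(sim_config):
    return generate_protocol(sim_config)


@pytest.fixture
def sim_records(sim_protocol, sim_config):
    return simulate_responses(sim_protocol, sim_config)
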