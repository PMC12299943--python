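# surveygraph

Schema-driven standardization for research questionnaires.

Clinical and behavioral studies collect most of their data through surveys,
yet the instruments themselves — the questions, response scales, skip logic
and scoring rules — are usually trapped in platform-specific exports or
Word documents. When a scale quietly changes between study waves
(a 5-point Likert becomes a 7-point one, a branching condition is fixed, a
typo is corrected), longitudinal data become hard to interpret and impossible
to audit. `surveygraph` addresses this for study teams, data managers and
archive curators by treating the questionnaire itself as versioned,
validated, linked data.

## The model

An instrument is a nested graph, **protocol > activity > item**:

- a **protocol** orders one or more **activities** (questionnaires), each
  optionally gated by a visibility expression — so a follow-up assessment
  can be triggered adaptively when a computed score crosses a threshold;
- an **activity** orders **items** (questions) under unique variable names,
  gates them with branching logic, and defines **compute rules** such as a
  subscale score `anxiety_score = mean(q1, q2, q3, q4, q5)`;
- an **item** carries its question text (a per-language map), an input type
  (Likert radio, drop-down, multi-select checkbox, bounded integer, free
  text, date, media capture, …) and **response options**: an ordered choice
  list or numeric bounds plus designated missing codes.

Every document is serialized canonically (sorted keys, fixed indentation)
and pinned by a content digest, computed bottom-up so the protocol digest
transitively identifies the exact content of the whole tree — an immutable
version pin. Each response record embeds the pinned item/activity/protocol
IRIs, so any answer can be traced to the exact schema version in force when
it was collected.

Expressions use a small C-like language with explicit missing-value
semantics: arithmetic touching a missing value is missing, comparisons
touching one are false, aggregates (`sum`, `mean`, `sd`, `min`, `max`,
`count`) skip missing arguments, and `sd` is the sample standard deviation
(n−1). Declared missing codes ("prefer not to answer") evaluate as missing,
so skipped items never corrupt a score.

Around this core the package provides:

- **validation** — structural and semantic diagnostics with a closed code
  set (range violations against inclusive bounds such as ages 18–99,
  controlled-vocabulary checks such as mild/moderate/severe, dangling
  references, compute-rule cycles, unknown expression variables, …);
- **converters** — REDCap data dictionary in/out (including branching-logic
  translation), FHIR R4 Questionnaire, BIDS phenotype TSV + JSON sidecar,
  and flat common-data-elements submission tables driven by a YAML mapping;
- **semantic diffing** — classified change reports between protocol
  versions (`item_added`, `item_removed`, `wording`, `response_scale`,
  `logic`, `scoring`, `reordered`, `metadata`), comparing expressions at
  AST level so formatting edits are not noise;
- **a simulator** — deterministic synthetic protocols, single-class
  mutations, and respondents who honour the branching logic, so the whole
  pipeline is testable without any external data.

## Worked example

```sh
$ surveygraph simulate study --seed 11 --respondents 5 --responses-out answers
wrote protocol (15 nodes) to study
wrote 47 response record(s) to answers

$ surveygraph score study answers
respondent,act1_score,act2_score
p001,2.0,1.5
p002,3.0,3.0
p003,1.0,2.6666666666666665
p004,2.0,2.0
p005,2.0,2.0
```

The protocol tree under `study/` holds one JSON-LD document per node
(`protocol.jsonld`, `activities/act1/activity.jsonld`,
`activities/act1/items/act1_q1.jsonld`, …). Each respondent's file under
`answers/` pins the document digests it was answered against. The score
table evaluates each activity's compute rule — here the mean of the first
five Likert items (codes 0–4), so `p001`'s `act1_score` of `2.0` means
"Moderately" on average; respondents who declined items are averaged over
the answers they did give.

Converting and auditing:

```sh
$ surveygraph to-redcap study dict.csv
$ head -2 dict.csv
Variable / Field Name,Form Name,...
act1_q1,act1,,radio,Feeling easily annoyed or irritable (act1_q1),"0, Not at all | 1, A little | 2, Moderately | 3, Quite a bit | 4, Extremely",...
```

```python
>>> import surveygraph as sg
>>> p1 = sg.load_protocol("study")
>>> p2 = sg.mutate_protocol(p1, "response_scale", seed=2)
>>> print(sg.render_report(sg.diff_protocols(p1, p2), "text"))
sha256-0fcf4a5a424c274d -> sha256-c0e6ada87ff7bb0a: 1 change(s)
  [response_scale] activities/act1/items/act1_q1: '5 options' -> '7 options'
```

The report pinpoints a 5-point scale that became a 7-point one — exactly
the kind of silent instrument drift that breaks longitudinal comparability.

`surveygraph new <dir>` scaffolds a starter protocol (a screening activity
with a bounded age field, a severity vocabulary, a five-item anxiety block
with a computed subscore, and an adaptively shown follow-up) to edit by
hand. `surveygraph --help` lists all subcommands.

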