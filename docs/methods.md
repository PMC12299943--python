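# Methods

This note documents the model behind `surveygraph`, the choices made where
the design was genuinely open, and what the test evidence does and does not
show.

## Schema graph and versioning

An instrument is a three-level graph — protocol > activity > item — stored
as one JSON-LD document per node. Documents are written canonically: UTF-8,
sorted keys, 2-space indent, LF line endings. Canonical form is what makes
version pins meaningful: two semantically identical documents are
byte-identical, so a content digest (SHA-256 over the canonical form with
the document's own `@id` removed, truncated to 16 hex characters and
prefixed `sha256-`) is a stable identity. Digests are assigned bottom-up:
item documents are digested first, activity documents embed the pinned item
IRIs and are digested in turn, and the protocol pins the activities — a
Merkle construction, so the protocol digest transitively identifies every
byte of the tree. This plays the role that commit pins on a hosting service
play in production deployments, while keeping the package fully offline;
semantic tags can be used in place of digests where a human-readable version
is wanted. Identifiers use the form `<base>/v/<version>/<path>`; the literal
`/v/` marker makes parsing unambiguous without registry lookups.

The 16-hex truncation (64 bits) is a deliberate trade of collision margin
for readable IRIs; at the scale of instruments a study maintains (thousands
of documents, not billions) the collision probability is negligible.

Documents reference a shipped `@context` (in `surveygraph/data/`), itself
pinned by digest in every file, so the vocabulary a file was written against
is part of its provenance. The package treats documents as plain JSON with
JSON-LD conventions (`@context`/`@id`/`@type`); no network dereferencing is
ever performed — that is a hard requirement, not an optimization.

Response records are written one file per respondent per activity. The
alternative (one aggregate file per activity) would be friendlier to bulk
export but worse for incremental collection and per-participant withdrawal;
per-respondent files keep each write independent.

## Expression language

Branching logic and computed subscores need a small, analyzable language,
not a general one. The
grammar is C-like with standard precedence (unary > `* / %` > `+ -` >
comparisons > `&&` > `||`), aggregate calls (`sum`, `mean`, `sd`, `min`,
`max`, `count`) and the predicates `isMissing(x)` and `has(x, v)` for
multiselect membership. Two properties drive the design: every expression
exposes its exact referenced-variable set (enabling static validation and
dependency ordering), and serialization∘parsing is a fixed point (enabling
AST-level diffing where whitespace is never a change).

Missing-value semantics are fixed once, centrally:

- arithmetic touching a missing value is missing (poison);
- a comparison touching one is **false** — a gate on an unanswered question
  simply stays closed;
- `&&`, `||`, `!` treat missing as false, consistently with comparisons;
- aggregates skip missing arguments; `count` counts the non-missing;
  `sum/mean/min/max` of zero non-missing arguments are missing; `sd` is the
  sample standard deviation (n−1) and needs at least two values;
- division or modulo by zero is missing rather than an error — a partial
  score should degrade, not crash a session;
- values equal to a declared missing code are bound as missing, which is
  what makes `isMissing` true for "declined" answers.

Visibility expressions must evaluate to a boolean; numbers are not truthy
(a `1` where a condition was meant is almost always a bug, and silently
truthy behavior would mask it). Type errors (strings in arithmetic) raise
rather than propagate.

Computed variables are evaluated in topological order of their mutual
dependencies, so chained scores resolve; a genuine cycle raises an error
naming the loop (the validator reports the same condition as a `SCORE_CYCLE`
finding before evaluation is ever attempted).

## Validation

Diagnostics are values (`Finding(severity, code, path, message)`), never
exceptions, so one pass reports everything; the list is sorted by path then
code so output is diffable. The code set is closed and documented in
`surveygraph/validate.py`; every code has a dedicated triggering fixture in
the test suite. Numeric bounds are inclusive — an age constraint of 18–99
accepts both endpoints, matching common survey practice. Out-of-set values
against *numeric* choice scales are classed as range problems; against
*string* vocabularies as controlled-vocabulary problems. A response set
spanning several protocol versions is a warning (`VERSION_MIX`), not an
error: mixed-version data is interpretable precisely because records are
version-pinned, but it deserves a flag.

## REDCap bridge

Import maps each form to an activity and each row to an item under the
standard 18-column dictionary template; `calc` rows become compute rules,
`descriptive` rows and section headers become static-display items. The
logic translator maps `[var]` → `var`, `=`/`<>` → `==`/`!=`,
`and`/`or` → `&&`/`||`, and the checkbox idiom `[var(3)] = '1'` →
`has(var, "3")` (negated for `= '0'`/`<> '1'`). Export is the inverse on
the supported subset; `mean`/`sum` in compute rules are lowered to explicit
arithmetic (`([a] + [b] + [c]) / 3`) since REDCap calc fields have no
aggregate functions, while `sd` and aggregate calls in *branching* logic are
refused loudly (an export error naming the item) rather than silently
dropped. REDCap-only metadata (field notes, matrix groups, annotations) is
carried as opaque item extras so it survives a round trip without being
modeled. The reader tolerates CRLF and a UTF-8 BOM, as found in files
exported from production systems.

Response export follows REDCap conventions: one row per respondent, one
column per variable, checkbox variables expanded to `var___code` indicator
columns, and hidden or unanswered cells left empty — never `0`, which would
fabricate a negative answer.

## Exports

**FHIR** (R4 Questionnaire, plain JSON resource shape): choice items carry
`answerOption` codings; multiselects set `repeats`; visibility that is a
conjunction of single-variable comparisons becomes `enableWhen` with
`enableBehavior: all` (with `has(var, code)` mapping to an `answerCoding`
test). Anything richer is *omitted with a logged warning* and recorded in
an extension on the item — degraded, never silent. Computed variables are
not exported to FHIR: a Questionnaire describes the instrument, not derived
data. An internal structural checker (resource type, status, unique linkIds,
answer presence in enableWhen) guards every emitted resource.

**BIDS phenotype**: per-activity TSV with columns `participant_id`, item
variables in declared order, then computed variables; missing and hidden
cells are `n/a` per the BIDS convention. The JSON sidecar describes each
column (question text, `Levels` for choice maps, `Units` where declared);
computed columns are flagged `"Derivative": true` — they are exported
because they are data a consumer wants, and flagged because they are not
raw answers.

**CDE tables**: archives differ in their templates, so the mapping
(template name, activity, variable → element names, sources for fixed
metadata columns) is a user-supplied YAML config with a shipped example;
`subjectkey` and `interview_date` derive from the respondent id and latest
answer timestamp. Unmapped items are excluded with a warning listing them;
a missing answer for a mapped element yields an empty cell plus a warning.

## Diffing

Items are matched across versions by variable name; a renamed variable
therefore appears as removed + added, which is the honest reading absent
any rename annotation. Expressions are compared at AST level with numeric
literal normalization (`2` ≡ `2.0`), so formatting edits produce no
entries. Question/label text changes are `wording` (compared after
whitespace normalization; changes confined to a non-default language carry
the language code); choice-set or bounds changes are `response_scale` with
a cardinality summary ("5 → 7 options"); visibility and compute-rule AST
changes are `logic` and `scoring`; an order permutation over an equal
variable set is `reordered`; protocol/activity descriptive fields are
`metadata`.

## Simulator

The generator's defaults define the study conditions used throughout the
tests: 2 activities × 6 items — a leading run of 5-point Likert radios
(codes 0–4), one bounded integer item (18–99), one 3-choice multiselect,
one free-text item — a mean-of-first-five compute rule per activity (over
the available Likert items when fewer than five), branching fraction 0.3
(each eligible item gated on an earlier answer with that probability, with
at least one gate guaranteed per activity), missing code −9 used at rate
0.1, and 100 respondents. Later activities are gated on the previous
activity's score, exercising adaptive triggering. Values are sampled
uniformly; no psychometric structure (factor loadings, item correlations,
response styles) is modelled — passing tests therefore demonstrate
structural and computational correctness, not realism of simulated scores.

Branching in generated protocols only references *earlier* items, so a
single in-order pass is an exact evaluation order and the answered-set =
visible-set fixed point is a meaningful invariant: re-evaluating all gates
on a respondent's final bindings reproduces exactly the set of items they
answered. Mutations (`mutate_protocol`) apply exactly one semantic change
of a requested class and keep the graph valid (e.g. only unreferenced
variables are removable), which is what makes the single-entry diff
property testable.

Determinism: all randomness flows through `random.Random(seed)`; identical
configurations yield byte-identical saved trees and response files.
Timestamps are derived arithmetically from respondent/item indices, not
from the clock.

## Problem sizes and numerical notes

The test suite and the acceptance script use 50 protocols for round-trip
checks, 20 small activities (≤6 items × 3 values, exhaustively enumerated
with an unanswered state per item — about 27,000 assignments) for oracle
equivalence, 1,000 random vectors for aggregate formulas, 8 × 20
protocol/mutation pairs for diff detection, and 100 respondents for the
fixed-point check; together they run in seconds. Aggregates are computed
with direct summation — at questionnaire scale (tens of arguments)
compensated summation would be indistinguishable, and the oracle comparison
tolerance of 1e-12 reflects plain float64 arithmetic, not a looser model.

## Known limitations

- No network IRI dereferencing, hosting, or Git operations; version pinning
  is local-content-digest based by design.
- REDCap matrix groups, repeating instruments, action tags and the API are
  out of scope; matrix metadata passes through opaquely.
- FHIR export targets the R4 Questionnaire resource only (no
  QuestionnaireResponse, no server interaction).
- The expression language is deliberately small; there is no date
  arithmetic and no cross-activity aggregate beyond referencing computed
  scores.
- Language-map support is syntactic (BCP-47 well-formedness), with
  default-language fallback; no translation management.
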