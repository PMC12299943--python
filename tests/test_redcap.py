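"""REDCap bridge: dictionary import/export, branching translation, responses."""

import io
import itertools

import pytest

from surveygraph import (
    ComputeRule,
    ExportError,
    ItemRef,
    TranslationError,
    back_translate,
    evaluate,
    export_data_dictionary,
    export_responses,
    import_data_dictionary,
    generate_protocol,
    parse_expression,
    serialize,
    simulate_responses,
    translate_branching,
    validate_protocol,
    SimConfig,
)
from surveygraph.redcap import HEADERS, ConversionError, parse_choices

from conftest import make_activity, make_item, make_protocol


def _dict_csv(rows):
    out = io.StringIO()
    import csv

    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(HEADERS)
    for row in rows:
        full = {h: "" for h in HEADERS}
        full.update(row)
        writer.writerow([full[h] for h in HEADERS])
    return io.StringIO(out.getvalue())


TEN_FIELD_FORM = [
    {"Variable / Field Name": "age", "Form Name": "intake", "Field Type": "text",
     "Field Label": "Age", "Text Validation Type OR Show Slider Number": "integer",
     "Text Validation Min": "18", "Text Validation Max": "99"},
    {"Variable / Field Name": "consent", "Form Name": "intake", "Field Type": "yesno",
     "Field Label": "Consent given?"},
    {"Variable / Field Name": "mood", "Form Name": "intake", "Field Type": "radio",
     "Field Label": "Mood", "Choices, Calculations, OR Slider Labels":
         "0, Not at all | 1, Several days | 2, More than half the days | 3, Nearly every day"},
    {"Variable / Field Name": "meds", "Form Name": "intake", "Field Type": "checkbox",
     "Field Label": "Medications", "Choices, Calculations, OR Slider Labels":
         "1, SSRI | 2, SNRI | 3, Other"},
    {"Variable / Field Name": "meds_other", "Form Name": "intake", "Field Type": "text",
     "Field Label": "Other medication",
     "Branching Logic (Show field only if...)": "[meds(3)] = '1'"},
    {"Variable / Field Name": "mood_why", "Form Name": "intake", "Field Type": "notes",
     "Field Label": "Tell us more",
     "Branching Logic (Show field only if...)": "[mood] >= 2 and [consent] = 1"},
    {"Variable / Field Name": "height", "Form Name": "intake", "Field Type": "text",
     "Field Label": "Height (m)", "Text Validation Type OR Show Slider Number": "number"},
    {"Variable / Field Name": "weight", "Form Name": "intake", "Field Type": "text",
     "Field Label": "Weight (kg)", "Text Validation Type OR Show Slider Number": "number"},
    {"Variable / Field Name": "bmi", "Form Name": "intake", "Field Type": "calc",
     "Field Label": "BMI", "Choices, Calculations, OR Slider Labels":
         "[weight] / ([height] * [height])"},
    {"Variable / Field Name": "visit_date", "Form Name": "intake", "Field Type": "text",
     "Field Label": "Visit date", "Text Validation Type OR Show Slider Number": "date_ymd"},
]


class TestImport:
    def test_counts_for_ten_field_form(self):
        protocol = import_data_dictionary(_dict_csv(TEN_FIELD_FORM))
        assert len(protocol.activity_order) == 1
        act = protocol.activities()[0]
        assert len(act.item_order) == 9  # calc row becomes a rule, not an item
        assert len(act.compute_rules) == 1
        n_vis = sum(1 for r in act.item_order if r.visibility is not None)
        assert n_vis == 2

    def test_integer_validation_becomes_bounds(self):
        protocol = import_data_dictionary(_dict_csv(TEN_FIELD_FORM))
        age = protocol.activities()[0].get_item_ref("age")
        assert age.item.input_type == "integer"
        assert age.item.response_options.min_value == 18
        assert age.item.response_options.max_value == 99

    def test_choices_string_parsed_in_order(self):
        choices = parse_choices("0, Not at all | 1, Several days", row=2)
        assert [(c.value, c.label.get("en")) for c in choices] == [
            (0, "Not at all"),
            (1, "Several days"),
        ]

    def test_field_type_mapping(self):
        protocol = import_data_dictionary(_dict_csv(TEN_FIELD_FORM))
        act = protocol.activities()[0]
        types = {r.variable_name: r.item.input_type for r in act.item_order}
        assert types["consent"] == "radio"  # yesno
        assert types["meds"] == "multiselect"
        assert types["mood_why"] == "textarea"
        assert types["visit_date"] == "date"
        consent = act.get_item_ref("consent").item
        assert [(c.value, c.label.get("en")) for c in consent.response_options.choices] == \
               [(1, "Yes"), (0, "No")]

    def test_unknown_field_type_names_row(self):
        rows = [dict(TEN_FIELD_FORM[0])]
        rows[0]["Field Type"] = "hologram"
        with pytest.raises(ConversionError) as exc:
            import_data_dictionary(_dict_csv(rows))
        assert "hologram" in str(exc.value)

    def test_malformed_choices_rejected(self):
        rows = [dict(TEN_FIELD_FORM[2])]
        rows[0]["Choices, Calculations, OR Slider Labels"] = "0 Not at all | 1 Several"
        with pytest.raises(ConversionError):
            import_data_dictionary(_dict_csv(rows))

    def test_imported_protocol_validates_clean(self):
        protocol = import_data_dictionary(_dict_csv(TEN_FIELD_FORM))
        assert [f for f in validate_protocol(protocol) if f.severity == "error"] == []

    def test_bom_and_crlf_tolerated(self):
        text = _dict_csv(TEN_FIELD_FORM).getvalue().replace("\n", "\r\n")
        protocol = import_data_dictionary(io.StringIO("﻿" + text))
        assert len(protocol.activities()[0].item_order) == 9


class TestBranchingTranslation:
    @pytest.mark.parametrize(
        "redcap, expected",
        [
            ("[age] >= 18 and [consent] = '1'", 'age >= 18 && consent == "1"'),
            ("[meds(2)] = '1'", 'has(meds, "2")'),
            ("[score] <> 3 or [x] < 2", "score != 3 || x < 2"),
            ("[a] = 1 AND [b] = 2", "a == 1 && b == 2"),
            ("[meds(3)] <> '1'", '!has(meds, "3")'),
        ],
    )
    def test_translation_table(self, redcap, expected):
        assert serialize(translate_branching(redcap).ast) == expected

    def test_unparseable_fragment_quoted_in_error(self):
        with pytest.raises(TranslationError) as exc:
            translate_branching("[a] >= and or")
        assert "[a] >= and or" in str(exc.value)

    @pytest.mark.parametrize(
        "logic, variables",
        [
            ("[age] >= 18 and [consent] = '1'", {"age": [17, 18, 30], "consent": ["0", "1"]}),
            ("[score] <> 3 or [x] < 2", {"score": [2, 3], "x": [1, 2, 3]}),
            ("[a] = 1 or [b] = 2 and [c] <> 0", {"a": [0, 1], "b": [1, 2], "c": [0, 1]}),
        ],
    )
    def test_round_trip_is_logically_equivalent(self, logic, variables):
        """back-translate(translate(L)) has the same truth table as L."""
        first = translate_branching(logic)
        back = back_translate(first)
        second = translate_branching(back)
        names = sorted(variables)
        for combo in itertools.product(*(variables[n] for n in names)):
            bindings = dict(zip(names, combo))
            assert evaluate(first, bindings) == evaluate(second, bindings), bindings


class TestExport:
    def test_round_trip_identity_on_simulated_dictionaries(self):
        for seed in range(1, 11):
            d1 = export_data_dictionary(generate_protocol(SimConfig(seed=seed)))
            d2 = export_data_dictionary(import_data_dictionary(io.StringIO(d1)))
            assert d1 == d2, f"seed {seed}"

    def test_round_trip_identity_on_handcrafted_dictionary(self):
        d0 = _dict_csv(TEN_FIELD_FORM).getvalue()
        d1 = export_data_dictionary(import_data_dictionary(io.StringIO(d0)))
        d2 = export_data_dictionary(import_data_dictionary(io.StringIO(d1)))
        assert d1 == d2
        # normalization: original differs from d1 only in stated ways
        assert d0.count("\n") == d1.count("\n")

    def test_multiselect_becomes_one_checkbox_row(self):
        protocol = import_data_dictionary(_dict_csv(TEN_FIELD_FORM))
        text = export_data_dictionary(protocol)
        rows = [r for r in text.splitlines() if r.startswith("meds,")]
        assert len(rows) == 1
        assert "checkbox" in rows[0]
        assert rows[0].count("|") == 2  # 3 choices

    def test_aggregate_visibility_is_an_export_error(self):
        act = make_activity(
            "a",
            [
                ItemRef(variable_name="q1", item=make_item("q1")),
                ItemRef(variable_name="q2", item=make_item("q2")),
                ItemRef(variable_name="q3", item=make_item("q3"),
                        visibility="mean(q1, q2) > 1"),
            ],
        )
        with pytest.raises(ExportError) as exc:
            export_data_dictionary(make_protocol([act]))
        assert "q3" in str(exc.value)

    def test_mean_rule_lowers_to_calc_arithmetic(self):
        act = make_activity(
            "a",
            [ItemRef(variable_name=f"q{i}", item=make_item(f"q{i}")) for i in (1, 2, 3)],
            [ComputeRule(target="s", expression="mean(q1, q2, q3)")],
        )
        text = export_data_dictionary(make_protocol([act]))
        calc_row = next(r for r in text.splitlines() if r.startswith("s,"))
        assert "([q1] + [q2] + [q3]) / 3" in calc_row

    def test_sd_rule_is_untranslatable(self):
        act = make_activity(
            "a",
            [ItemRef(variable_name=f"q{i}", item=make_item(f"q{i}")) for i in (1, 2)],
            [ComputeRule(target="s", expression="sd(q1, q2)")],
        )
        with pytest.raises(ExportError):
            export_data_dictionary(make_protocol([act]))


class TestResponseExport:
    def _small(self):
        act = make_activity(
            "a",
            [ItemRef(variable_name=v, item=make_item(v)) for v in ("q1", "q2", "q3")],
        )
        return make_protocol([act])

    def _rec(self, protocol, respondent, var, value):
        from surveygraph import ResponseRecord

        act = protocol.activities()[0]
        ref = act.get_item_ref(var)
        return ResponseRecord(respondent, protocol.id, act.id, ref.item.id, var, value,
                              "2025-01-01T09:00:00Z")

    def test_wide_layout(self):
        p = self._small()
        records = [self._rec(p, r, v, 1) for r in ("pa", "pb") for v in ("q1", "q2", "q3")]
        text = export_responses(records, p)
        lines = text.splitlines()
        assert lines[0] == "record_id,q1,q2,q3"
        assert len(lines) == 3  # header + 2 respondents

    def test_multiselect_expands_to_indicator_columns(self, sim_protocol, sim_config):
        records = simulate_responses(sim_protocol, SimConfig(seed=sim_config.seed, n_respondents=20))
        text = export_responses(records, sim_protocol)
        header = text.splitlines()[0].split(",")
        ms_cols = [c for c in header if "___" in c]
        assert ms_cols  # simulator always has a multiselect item
        chooser = next(
            r for r in records if isinstance(r.value, list)
        )
        row = next(l for l in text.splitlines() if l.startswith(chooser.respondent + ","))
        cells = dict(zip(header, row.split(",")))
        var = chooser.variable_name
        for code in (1, 2, 3):
            expected = "1" if code in chooser.value else "0"
            assert cells[f"{var}___{code}"] == expected

    def test_hidden_cells_are_empty_not_zero(self):
        p = self._small()
        records = [self._rec(p, "pa", "q1", 2)]  # q2/q3 unanswered
        text = export_responses(records, p)
        assert text.splitlines()[1] == "pa,2,,"
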