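"""FHIR Questionnaire, BIDS phenotype, and CDE exports."""

import json
import logging

import pytest

from surveygraph import (
    CdeMapping,
    ConfigurationError,
    ComputeRule,
    ItemRef,
    ResponseRecord,
    canonical_dumps,
    check_fhir_questionnaire,
    new_protocol,
    to_bids_phenotype,
    to_cde,
    to_fhir_questionnaire,
    SimConfig,
    simulate_responses,
)
from surveygraph.exporters import UNTRANSLATABLE_VIS_EXT

from conftest import make_activity, make_item, make_protocol


def _rec(protocol, act_name, respondent, var, value, when="2025-03-01T10:00:00Z"):
    act = protocol.get_activity(act_name)
    ref = act.get_item_ref(var)
    return ResponseRecord(respondent, protocol.id, act.id, ref.item.id, var, value, when)


class TestFhir:
    def test_radio_item_maps_to_choice_with_answer_options(self):
        act = make_activity("a", [ItemRef(variable_name="q1", item=make_item("q1"))])
        p = make_protocol([act])
        resource = to_fhir_questionnaire(p.activities()[0], p)
        item = resource["item"][0]
        assert resource["resourceType"] == "Questionnaire"
        assert item["type"] == "choice"
        assert len(item["answerOption"]) == 4
        assert item["answerOption"][0]["valueCoding"]["code"] == "0"

    def test_conjunction_becomes_enable_when_all(self):
        act = make_activity(
            "a",
            [
                ItemRef(variable_name="q1", item=make_item("q1")),
                ItemRef(variable_name="q2", item=make_item("q2")),
                ItemRef(variable_name="q3", item=make_item("q3"),
                        visibility="q1 == 2 && q2 >= 1"),
            ],
        )
        p = make_protocol([act])
        resource = to_fhir_questionnaire(p.activities()[0], p)
        q3 = resource["item"][2]
        assert len(q3["enableWhen"]) == 2
        assert q3["enableBehavior"] == "all"
        assert q3["enableWhen"][0] == {"question": "q1", "operator": "=", "answerInteger": 2}
        assert q3["enableWhen"][1] == {"question": "q2", "operator": ">=", "answerInteger": 1}

    def test_untranslatable_visibility_degrades_with_warning(self, caplog):
        act = make_activity(
            "a",
            [
                ItemRef(variable_name="q1", item=make_item("q1")),
                ItemRef(variable_name="q2", item=make_item("q2")),
                ItemRef(variable_name="q3", item=make_item("q3"),
                        visibility="mean(q1, q2) > 1"),
            ],
        )
        p = make_protocol([act])
        with caplog.at_level(logging.WARNING, logger="surveygraph.exporters"):
            resource = to_fhir_questionnaire(p.activities()[0], p)
        q3 = resource["item"][2]
        assert "enableWhen" not in q3
        assert any("mean(q1, q2) > 1" in r.getMessage() for r in caplog.records)
        assert q3["extension"][0]["url"] == UNTRANSLATABLE_VIS_EXT
        assert check_fhir_questionnaire(resource) == []

    def test_multiselect_repeats_and_checkbox_enable_when(self, sim_protocol):
        for act in sim_protocol.activities():
            resource = to_fhir_questionnaire(act, sim_protocol)
            assert check_fhir_questionnaire(resource) == []
            by_id = {i["linkId"]: i for i in resource["item"]}
            ms = next(i for i in resource["item"] if i.get("repeats"))
            assert ms["type"] == "choice"

    def test_computed_variables_not_in_fhir(self, sim_protocol):
        act = sim_protocol.activities()[0]
        resource = to_fhir_questionnaire(act, sim_protocol)
        link_ids = {i["linkId"] for i in resource["item"]}
        assert not any(r.target in link_ids for r in act.compute_rules)

    def test_structural_checker_catches_duplicates(self):
        broken = {
            "resourceType": "Questionnaire",
            "status": "active",
            "item": [{"linkId": "a", "type": "string"}, {"linkId": "a", "type": "string"}],
        }
        assert any("unique" in p for p in check_fhir_questionnaire(broken))
        assert check_fhir_questionnaire({"resourceType": "Patient"}) != []


class TestBids:
    def _fixture(self):
        act = make_activity(
            "phq",
            [ItemRef(variable_name=v, item=make_item(v)) for v in ("q1", "q2")]
            + [ItemRef(variable_name="q3", item=make_item("q3"), visibility="q1 >= 2")],
            [ComputeRule(target="total", expression="sum(q1, q2, q3)")],
        )
        return make_protocol([act])

    def test_tsv_shape_and_sidecar_accounting(self, tmp_path):
        p = self._fixture()
        records = [
            _rec(p, "phq", "s1", "q1", 2), _rec(p, "phq", "s1", "q2", 1),
            _rec(p, "phq", "s1", "q3", 3),
            _rec(p, "phq", "s2", "q1", 0), _rec(p, "phq", "s2", "q2", 1),
        ]
        to_bids_phenotype(p, records, tmp_path)
        lines = (tmp_path / "phq.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["participant_id", "q1", "q2", "q3", "total"]
        assert len(lines) == 3  # header + 2 participants
        sidecar = json.loads((tmp_path / "phq.json").read_text())
        assert len(lines[0].split("\t")) == len(sidecar) + 1

    def test_levels_equal_choice_map(self, tmp_path):
        p = self._fixture()
        to_bids_phenotype(p, [_rec(p, "phq", "s1", "q1", 1)], tmp_path)
        sidecar = json.loads((tmp_path / "phq.json").read_text())
        assert sidecar["q1"]["Levels"] == {
            "0": "Not at all", "1": "Several days",
            "2": "More than half the days", "3": "Nearly every day",
        }
        assert sidecar["total"]["Derivative"] is True

    def test_hidden_item_written_as_na(self, tmp_path):
        p = self._fixture()
        records = [_rec(p, "phq", "s1", "q1", 0), _rec(p, "phq", "s1", "q2", 1)]
        # q3 hidden because q1 < 2
        to_bids_phenotype(p, records, tmp_path)
        row = (tmp_path / "phq.tsv").read_text().splitlines()[1].split("\t")
        assert row == ["s1", "0", "1", "n/a", "1.0"]  # sum skips the missing q3

    def test_export_is_read_only(self, tmp_path, sim_protocol, sim_config):
        from surveygraph import pin_versions

        records = simulate_responses(sim_protocol, SimConfig(seed=sim_config.seed, n_respondents=5))
        before = sim_protocol.id.version
        snapshot = canonical_dumps([r.value for r in records])
        to_bids_phenotype(sim_protocol, records, tmp_path)
        pin_versions(sim_protocol)
        assert sim_protocol.id.version == before
        assert canonical_dumps([r.value for r in records]) == snapshot


class TestCde:
    def _mapping(self):
        return CdeMapping(
            template="anxiety01",
            activity="screening",
            items={f"q{i}": f"elem{i}" for i in range(1, 6)},
            sources={"interview_age": "age"},
        )

    def _records(self, p, respondents=("s1", "s2", "s3")):
        out = []
        for resp in respondents:
            out.append(_rec(p, "screening", resp, "age", 44))
            for i in range(1, 6):
                out.append(_rec(p, "screening", resp, f"q{i}", 1))
        return out

    def test_row_and_column_counts(self):
        p = new_protocol()
        text, warnings = to_cde(self._records(p), p, self._mapping())
        lines = text.splitlines()
        assert len(lines) == 4  # header + 3 respondents
        assert len(lines[0].split(",")) == 4 + 5  # fixed metadata + mapped elements

    def test_unknown_variable_named_in_error(self):
        p = new_protocol()
        mapping = self._mapping()
        mapping.items["zz"] = "elem_zz"
        with pytest.raises(ConfigurationError) as exc:
            to_cde(self._records(p), p, mapping)
        assert "zz" in str(exc.value)

    def test_missing_answer_gives_empty_cell_and_warning(self):
        p = new_protocol()
        records = self._records(p, respondents=("s1",))
        records = [r for r in records if r.variable_name != "q5"]
        text, warnings = to_cde(records, p, self._mapping())
        row = text.splitlines()[1].split(",")
        assert row[-1] == ""
        assert sum("elem5" in w for w in warnings) == 1

    def test_unmapped_items_warned_once(self):
        p = new_protocol()
        _, warnings = to_cde(self._records(p), p, self._mapping())
        unmapped = [w for w in warnings if w.startswith("unmapped")]
        assert len(unmapped) == 1
        assert "severity" in unmapped[0]

    def test_fixed_metadata_sources(self):
        p = new_protocol()
        text, _ = to_cde(self._records(p, ("s9",)), p, self._mapping())
        header, row = [l.split(",") for l in text.splitlines()]
        cells = dict(zip(header, row))
        assert cells["subjectkey"] == "s9"
        assert cells["interview_age"] == "44"
        assert cells["interview_date"] == "2025-03-01"

    def test_shipped_example_mapping_works_with_scaffold(self):
        import importlib.resources

        p = new_protocol()
        ref = importlib.resources.files("surveygraph").joinpath("data/cde_example.yaml")
        mapping = CdeMapping.from_yaml(str(ref))
        text, _ = to_cde(self._records(p), p, mapping)
        assert "anx_subscale_mean" in text.splitlines()[0]
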