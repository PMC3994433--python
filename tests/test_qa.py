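"""Knowledge base loading, checklist derivation and the result print."""

import io
import json

import pytest

from flashdiff import __version__
from flashdiff.comparison import compare
from flashdiff.errors import ChecklistContractError, InvalidPattern, KBLoadError
from flashdiff.facility import DEFAULT_ROOMS
from flashdiff.qa import (BEAM_INFLUENCES, RAM_DEVIATION_BANNER, RunContext,
                          apply_output_filter, derive_checklist, load_kb,
                          render_report)
from flashdiff.validation import ValidationOptions, validate_pair

from conftest import make_kb


KB_TEXT = """#%flashdiff-kb 1
#%version: 2.3
#%facility_id: FAC-T
# dcu_id\tdevice_name\tinfluences\taffected_rooms
D1\tdipole-01\tenergy,position\tH1,H2
D2\tquadrupole-01\tfocus\tH1,H2
D3\tmonitor-01\tintensity,position\tG1
"""


class TestLoadKB:
    def test_well_formed_kb_loaded_fully(self):
        kb = load_kb(io.StringIO(KB_TEXT))
        assert len(kb) == 3
        assert kb.version == "2.3"
        assert kb.facility_id == "FAC-T"
        assert kb.entries["D1"].influences == {"energy", "position"}
        assert kb.entries["D3"].affected_rooms == {"G1"}

    def test_generated_kb_covers_inventory(self, desk_pair):
        model, *_ = desk_pair
        assert set(model.kb.entries) == set(model.dcu_ids)
        assert len(model.kb) == len(model.dcu_inventory)

    def test_kb_write_read_round_trip(self, desk_pair, tmp_path):
        model, *_ = desk_pair
        path = tmp_path / "facility.kb"
        model.kb.write(path)
        assert load_kb(path) == model.kb

    def test_duplicate_dcu_id_names_offender(self):
        text = KB_TEXT + "D1\tdipole-02\tenergy\tH1\n"
        with pytest.raises(KBLoadError) as err:
            load_kb(io.StringIO(text))
        assert err.value.code == "duplicate_dcu"
        assert err.value.entry == "D1"

    def test_unknown_influence_token_rejected(self):
        text = KB_TEXT + "D4\tdev\tcolour\tH1\n"
        with pytest.raises(KBLoadError) as err:
            load_kb(io.StringIO(text))
        assert err.value.code == "unknown_influence"

    def test_unknown_room_rejected(self):
        text = KB_TEXT + "D4\tdev\tenergy\tH9\n"
        with pytest.raises(KBLoadError) as err:
            load_kb(io.StringIO(text))
        assert err.value.code == "unknown_room"

    def test_empty_influence_set_rejected(self):
        text = KB_TEXT + "D4\tdev\t\tH1\n"
        with pytest.raises(KBLoadError) as err:
            load_kb(io.StringIO(text))
        assert err.value.code == "empty_influences"

    def test_malformed_line_rejected(self):
        with pytest.raises(KBLoadError) as err:
            load_kb(io.StringIO("just one field\n"))
        assert err.value.code == "bad_format"


def _brute_force_pairs(diffs, kb):
    """Independent oracle: union of influence×room products over changed DCUs."""
    pairs = set()
    for dcu_id in diffs.changed_dcu_ids:
        entry = kb.entries[dcu_id]
        for infl in entry.influences:
            for room in entry.affected_rooms:
                pairs.add((room, infl))
    return pairs


class TestDeriveChecklist:
    def test_empty_diffs_no_qa_required(self, tiny_pair):
        last, _, kb = tiny_pair
        checklist = derive_checklist(compare(last, last), kb)
        assert checklist.verdict == "no_qa_required"
        assert checklist.items == [] and not checklist.unresolved_dcus

    def test_single_focus_device_hits_its_rooms_only(self, tiny_pair):
        last, current, _ = tiny_pair  # change is on D1
        kb = make_kb(["D1", "D2"], influences=("focus",), rooms=("H1", "H2"))
        checklist = derive_checklist(compare(last, current), kb)
        assert checklist.verdict == "qa_required"
        assert checklist.required_pairs == {("H1", "focus"), ("H2", "focus")}
        assert "G1" not in checklist.rooms()

    def test_matches_brute_force_union_oracle(self, desk_pair):
        model, base, current, _ = desk_pair
        diffs = compare(base, current)
        checklist = derive_checklist(diffs, model.kb)
        assert checklist.required_pairs == _brute_force_pairs(diffs, model.kb)

    def test_unknown_device_escalates_to_full_qa(self, tiny_pair):
        last, current, _ = tiny_pair
        kb = make_kb(["D2"])  # D1 changed but unknown
        checklist = derive_checklist(compare(last, current), kb)
        assert checklist.verdict == "escalate_full_qa"
        assert checklist.unresolved_dcus == {"D1"}
        assert len(checklist.items) == len(BEAM_INFLUENCES) * len(DEFAULT_ROOMS)
        assert checklist.required_pairs == {
            (r.room_id, infl) for r in DEFAULT_ROOMS for infl in BEAM_INFLUENCES}

    def test_traceability_every_item_carries_triggers(self, desk_pair):
        model, base, current, _ = desk_pair
        diffs = compare(base, current)
        checklist = derive_checklist(diffs, model.kb)
        assert all(item.triggering_differences for item in checklist.items)
        traced = {d.dcu_id for item in checklist.items
                  for d in item.triggering_differences}
        assert traced == diffs.changed_dcu_ids

    def test_monotonic_adding_difference_never_removes_items(self, desk_pair):
        model, base, current, ledger = desk_pair
        diffs = compare(base, current)
        for k in range(1, len(diffs) + 1):
            from flashdiff.comparison import DifferenceSet
            partial = DifferenceSet(list(diffs.differences[:k]))
            sub = derive_checklist(partial, model.kb).required_pairs
            full = derive_checklist(diffs, model.kb).required_pairs
            assert sub <= full

    def test_contract_violation_raises(self, tiny_pair):
        last, current, kb = tiny_pair
        with pytest.raises(ChecklistContractError):
            derive_checklist(compare(last, current), kb,
                             checklist_permitted=False)


class TestOutputFilter:
    def test_empty_pattern_list_is_identity(self, desk_pair):
        _, base, current, _ = desk_pair
        diffs = compare(base, current)
        assert apply_output_filter(diffs, []).differences == diffs.differences

    def test_pattern_matching_nothing_empties_display(self, desk_pair):
        _, base, current, _ = desk_pair
        diffs = compare(base, current)
        assert len(apply_output_filter(diffs, ["NOPE-*"])) == 0

    def test_prefix_pattern_restricts_to_matching_ids(self, desk_pair):
        _, base, current, _ = desk_pair
        diffs = compare(base, current)
        shown = apply_output_filter(diffs, ["DCU-00*"])
        assert set(shown.differences) <= set(diffs.differences)
        assert all(d.dcu_id.startswith("DCU-00") for d in shown)

    def test_checklist_unaffected_by_any_filter(self, desk_pair):
        """Fail-safe: filters are display-only; checklist uses the full set."""
        model, base, current, _ = desk_pair
        diffs = compare(base, current)
        unfiltered = derive_checklist(diffs, model.kb)
        apply_output_filter(diffs, ["NOPE-*"])
        filtered_view = derive_checklist(diffs, model.kb)
        assert filtered_view.required_pairs == unfiltered.required_pairs

    def test_invalid_pattern_rejected(self, desk_pair):
        _, base, current, _ = desk_pair
        with pytest.raises(InvalidPattern):
            apply_output_filter(compare(base, current), ["  "])


class TestRenderReport:
    def _context(self, **kw):
        return RunContext(tool_version=__version__, kb_version="2.3", **kw)

    def test_diff_only_mode_has_no_checklist_and_says_so(self, tiny_pair):
        last, current, kb = tiny_pair
        report = validate_pair(last, current, kb)
        diffs = compare(last, current)
        text = render_report(None, diffs, report, self._context(ignore=True),
                             last=last, current=current)
        assert "DIFFERENCES" in text
        assert "NO QA CHECKLIST ISSUED" in text
        assert "QA CHECKLIST —" not in text

    def test_ram_banner_exactly_once_at_head(self, tiny_pair):
        last, current, kb = tiny_pair
        current.header.dump_type = "ram"
        opts = ValidationOptions(allow_ram=True)
        report = validate_pair(last, current, kb, opts)
        diffs = compare(last, current)
        checklist = derive_checklist(diffs, kb)
        for fmt in ("text", "json"):
            out = render_report(checklist, diffs, report,
                                self._context(allow_ram=True), last=last,
                                current=current, fmt=fmt)
            assert out.count(RAM_DEVIATION_BANNER) == 1
        text = render_report(checklist, diffs, report,
                             self._context(allow_ram=True), last=last,
                             current=current)
        assert text.splitlines()[0] == RAM_DEVIATION_BANNER

    def test_clean_empty_run_states_no_qa_required(self, tiny_pair):
        last, _, kb = tiny_pair
        report = validate_pair(last, last, kb)  # findings irrelevant here
        diffs = compare(last, last)
        checklist = derive_checklist(diffs, kb)
        text = render_report(checklist, diffs, report, self._context(),
                             last=last, current=last)
        assert "verdict: no_qa_required" in text
        assert "No QA required" in text

    def test_text_and_json_carry_same_content(self, desk_pair):
        model, base, current, _ = desk_pair
        report = validate_pair(base, current, model.kb,
                               ValidationOptions(grids=model.grids))
        diffs = compare(base, current)
        checklist = derive_checklist(diffs, model.kb)
        ctx = self._context()
        text = render_report(checklist, diffs, report, ctx, last=base,
                             current=current, fmt="text")
        doc = json.loads(render_report(checklist, diffs, report, ctx,
                                       last=base, current=current, fmt="json"))
        assert doc["checklist"]["verdict"] == checklist.verdict
        assert doc["differences"]["summary"]["total"] == len(diffs)
        assert base.header.payload_checksum in text
        assert doc["dumps"]["last"]["payload_checksum"] == \
            base.header.payload_checksum
        for ts in (doc["dumps"]["last"]["export_timestamp"],
                   doc["dumps"]["current"]["export_timestamp"]):
            assert ts in text
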