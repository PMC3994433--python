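"""Synthetic facility/dump generator: determinism, closure, corruption modes."""

import math

import pytest
from lxml import etree

from flashdiff.dumpio import compute_checksum, read_flashdump, write_flashdump
from flashdiff.errors import (InapplicableCorruption, MalformedXML,
                              SchemaViolation, UnresolvableTarget)
from flashdiff.facility import in_range
from flashdiff.synthetic import (CORRUPTION_FINDING, CORRUPTION_MODES,
                                 EditRequest, FULL_DCU_COUNT,
                                 apply_modifications, corrupt,
                                 generate_facility, generate_flashdump,
                                 generate_pair, random_plan)
from flashdiff.validation import ValidationOptions, validate_pair

from conftest import T0


class TestGenerateFacility:
    def test_full_scale_inventory_and_grids(self):
        model = generate_facility(seed=42, scale=1.0)
        assert len(model.dcu_inventory) == 177
        assert model.grids["proton"].energy.step_count == 255
        assert model.grids["carbon"].intensity.step_count == 8
        assert model.grids["proton"].gantry.interpolation_step_count == 36
        assert len(model.kb) == 177

    def test_determinism_same_seed_same_model(self):
        assert generate_facility(42, 0.1) == generate_facility(42, 0.1)

    @pytest.mark.parametrize("scale,expected", [(0.1, 18), (0.05, 9), (1.0, 177)])
    def test_scale_shrinks_inventory_by_ceiling(self, scale, expected):
        model = generate_facility(7, scale)
        assert len(model.dcu_inventory) == expected
        assert expected == math.ceil(scale * FULL_DCU_COUNT)

    def test_invalid_scale_rejected(self):
        for bad in (0.0, -1, 1.5):
            with pytest.raises(ValueError):
                generate_facility(1, bad)

    def test_minimum_one_step_per_axis(self):
        model = generate_facility(1, 0.001)
        for g in model.grids.values():
            for q in ("energy", "focus", "intensity"):
                assert g.axis(q).step_count >= 1

    def test_at_least_one_gantry_device(self):
        for seed in range(5):
            model = generate_facility(seed, 0.05)
            assert model.gantry_dcu_ids()


class TestGenerateFlashdump:
    def test_validates_against_bundled_xsd(self, desk_pair):
        _, base, _, _ = desk_pair
        # read_flashdump schema-validates; a clean parse is the assertion
        assert read_flashdump(write_flashdump(base)) == base

    def test_all_values_pass_in_range(self, desk_pair):
        model, base, _, _ = desk_pair
        for rec in base.records:
            for key, params in rec.settings.items():
                grid = model.grids[key.species]
                for name in ("energy", "focus", "intensity"):
                    assert in_range(grid, name, params[name].numeric_value)
                if key.node >= 0:
                    assert in_range(grid, "gantry_angle",
                                    params["gantry_angle"].numeric_value)

    def test_gantry_devices_carry_angle_nodes(self, desk_pair):
        model, base, _, _ = desk_pair
        gantry_ids = model.gantry_dcu_ids()
        n_nodes = model.grids["proton"].gantry.interpolation_step_count
        for rec in base.records:
            nodes = {k.node for k in rec.settings}
            if rec.dcu_id in gantry_ids:
                assert nodes == set(range(n_nodes))
            else:
                assert nodes == {-1}

    def test_seed_determinism_byte_identical(self):
        model = generate_facility(3, 0.03)
        d1 = generate_flashdump(model, 5, T0)
        d2 = generate_flashdump(model, 5, T0)
        assert write_flashdump(d1) == write_flashdump(d2)

    def test_same_seed_pair_at_two_times_is_identical_dumps(self):
        model = generate_facility(3, 0.03)
        from conftest import later
        d1 = generate_flashdump(model, 5, T0)
        d2 = generate_flashdump(model, 5, later(T0))
        report = validate_pair(d1, d2, model.kb,
                               ValidationOptions(grids=model.grids))
        assert [f.code for f in report.findings] == ["identical_dumps"]

    def test_different_seeds_different_checksums(self):
        """No digest collisions across 50 seed pairs."""
        model = generate_facility(3, 0.02)
        sums = {compute_checksum(generate_flashdump(model, s, T0).records)
                for s in range(50)}
        assert len(sums) == 50


class TestApplyModifications:
    def test_ledger_matches_plan_and_is_recovered(self, desk_pair):
        from flashdiff.comparison import DiffKind, compare
        model, base, current, ledger = desk_pair
        assert len(ledger) == 3
        diffs = compare(base, current)
        got = {(d.dcu_id, str(d.setting), d.parameter_name,
                d.old_value.canonical_text, d.new_value.canonical_text)
               for d in diffs.of_kind(DiffKind.CHANGED)}
        assert got == ledger.as_change_set()

    def test_empty_plan_still_fresh_dump(self, desk_pair):
        model, base, _, _ = desk_pair
        new, ledger = apply_modifications(base, [], seed=0, model=model)
        assert len(ledger) == 0
        assert new.header.export_timestamp > base.header.export_timestamp
        # empty edit: payload unchanged, so checksums agree
        assert new.header.payload_checksum == base.header.payload_checksum

    def test_out_of_range_request_produces_flaggable_value(self, desk_pair):
        model, base, _, _ = desk_pair
        rec = base.records[0]
        key = sorted(rec.settings)[0]
        req = EditRequest(rec.dcu_id, key, "energy", out_of_range=True)
        edited, ledger = apply_modifications(base, [req], seed=1, model=model)
        value = edited.record_map[rec.dcu_id].settings[key]["energy"]
        assert not in_range(model.grids[key.species], "energy",
                            value.numeric_value)
        report = validate_pair(base, edited, model.kb,
                               ValidationOptions(grids=model.grids))
        assert [f.code for f in report.findings] == ["out_of_range"]

    def test_in_range_random_edits_keep_pair_clean(self, desk_pair):
        model, base, current, _ = desk_pair
        report = validate_pair(base, current, model.kb,
                               ValidationOptions(grids=model.grids))
        assert report.findings == []

    def test_unresolvable_target_raises(self, desk_pair):
        model, base, _, _ = desk_pair
        key = sorted(base.records[0].settings)[0]
        with pytest.raises(UnresolvableTarget):
            apply_modifications(
                base, [EditRequest("DCU-NOPE", key, "energy")], model=model)
        with pytest.raises(UnresolvableTarget):
            apply_modifications(
                base, [EditRequest(base.records[0].dcu_id, key, "nope")],
                model=model)

    def test_duplicate_targets_rejected(self, desk_pair):
        model, base, _, _ = desk_pair
        key = sorted(base.records[0].settings)[0]
        req = EditRequest(base.records[0].dcu_id, key, "energy")
        with pytest.raises(UnresolvableTarget):
            apply_modifications(base, [req, req], model=model)

    def test_random_plan_deterministic_and_distinct(self, desk_pair):
        model, base, _, _ = desk_pair
        p1 = random_plan(model, base, 10, seed=4)
        p2 = random_plan(model, base, 10, seed=4)
        assert p1 == p2
        targets = {(r.dcu_id, r.setting, r.parameter_name) for r in p1}
        assert len(targets) == 10


class TestCorruption:
    @pytest.mark.parametrize("mode", CORRUPTION_MODES)
    def test_each_mode_triggers_exactly_its_finding(self, desk_pair, mode):
        model, base, current, _ = desk_pair
        expected = CORRUPTION_FINDING[mode]
        blast, bcur = corrupt((base, current), mode, seed=5)
        try:
            last = read_flashdump(blast)
            cur = read_flashdump(bcur)
        except MalformedXML:
            assert expected == "malformed_xml"
            return
        except SchemaViolation:
            assert expected == "schema_violation"
            return
        report = validate_pair(last, cur, model.kb,
                               ValidationOptions(grids=model.grids))
        assert sorted({f.code for f in report.findings}) == [expected]

    def test_pair_modes_require_a_pair(self, desk_pair):
        _, base, _, _ = desk_pair
        for mode in ("identical_pair", "stale_timestamp"):
            with pytest.raises(InapplicableCorruption):
                corrupt(base, mode)

    def test_single_dump_modes_accept_single_dump(self, desk_pair):
        _, base, _, _ = desk_pair
        data = corrupt(base, "bad_checksum")
        dump = read_flashdump(data)
        assert dump.header.payload_checksum != compute_checksum(dump.records)

    def test_schema_violation_output_is_well_formed(self, desk_pair):
        _, base, current, _ = desk_pair
        _, bcur = corrupt((base, current), "schema_violation")
        etree.fromstring(bcur)  # parses as XML, fails only the XSD
        with pytest.raises(SchemaViolation):
            read_flashdump(bcur)

    def test_unknown_mode_rejected(self, desk_pair):
        _, base, current, _ = desk_pair
        with pytest.raises(ValueError):
            corrupt((base, current), "gremlins")
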