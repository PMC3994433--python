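from datetime import datetime, timedelta, timezone

import pytest

from flashdiff.dumpio import (DCURecord, Flashdump, FlashdumpHeader,
                              ParameterValue, SettingKey)
from flashdiff.qa import KBEntry, KnowledgeBase
from flashdiff.synthetic import generate_pair

T0 = datetime(2025, 6, 1, 8, 0, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def desk_pair():
    """One deterministic desk-scale pair: model, base, edited dump, ledger."""
    return generate_pair(seed=11, scale=0.05, n_edits=3)


def make_dump(params_by_dcu, *, dump_type="flash", ts=T0, facility="FAC-T",
              species="proton", e=0, f=0, i=0):
    """Tiny hand-built dump: {dcu_id: {param: (value, unit)}} on one setting."""
    records = []
    for dcu_id, params in params_by_dcu.items():
        rec = DCURecord(dcu_id, f"dev-{dcu_id}", "dipole")
        rec.settings[SettingKey.make(species, e, f, i)] = {
            name: ParameterValue(str(val), unit)
            for name, (val, unit) in params.items()}
        records.append(rec)
    header = FlashdumpHeader(dump_type=dump_type, export_timestamp=ts,
                             facility_id=facility)
    return Flashdump(header, records).seal()


def make_kb(dcu_ids, facility="FAC-T", influences=("energy",),
            rooms=("H1", "H2")):
    entries = {d: KBEntry(d, f"dev-{d}", frozenset(influences),
                          frozenset(rooms)) for d in dcu_ids}
    return KnowledgeBase(entries, version="test-1", facility_id=facility)


def later(ts, hours=1):
    return ts + timedelta(hours=hours)


@pytest.fixture
def tiny_pair():
    """Minimal clean two-DCU pair with one numeric change."""
    last = make_dump({"D1": {"energy": (60.0, "MeV/u"), "magnet_current": (100.0, "A")},
                      "D2": {"energy": (60.0, "MeV/u")}})
    current = make_dump({"D1": {"energy": (60.0, "MeV/u"), "magnet_current": (101.5, "A")},
                         "D2": {"energy": (60.0, "MeV/u")}},
                        ts=later(T0))
    kb = make_kb(["D1", "D2"])
    return last, current, kb
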