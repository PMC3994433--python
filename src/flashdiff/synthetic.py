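"""Synthetic facility models, flashdump pairs and corrupted artifacts.

No real accelerator export is publicly available, so every other module is
exercised against generated data.  The generator emulates a representative
dual-species facility — 177 device control units, the standard MEFI grids,
two horizontal treatment rooms plus one gantry room — and emits flashdump
pairs together with an exact *injection ledger* of the edits that distinguish
them.  The ledger is the ground truth the diff engine is judged against: a
sound and complete comparison recovers it exactly.

Everything is seeded and fully deterministic: the same (seed, scale, plan)
yields byte-identical artifacts.  ``scale`` shrinks the inventory and the
MEFI grids proportionally so test corpora stay fast; scale 1 reproduces the
full facility constants.

Device classes and their parameter vocabularies are invented plausibly (the
device taxonomy of a real facility is not public) and kept in a module-level
table so they can be replaced wholesale.
"""

from __future__ import annotations

import copy
import json
import math
import random
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

from lxml import etree

from .dumpio import (DCURecord, Flashdump, FlashdumpHeader, ParameterValue,
                     SettingKey, write_flashdump)
from .errors import InapplicableCorruption, UnresolvableTarget
from .facility import (AxisSpec, BeamParameterGrid, DEFAULT_ROOMS, GantrySpec,
                       IonSpecies, TreatmentRoom, angle_nodes, default_grids,
                       step_value)
from .qa import KBEntry, KnowledgeBase

__all__ = [
    "FULL_DCU_COUNT",
    "DEVICE_CLASSES",
    "FacilityModel",
    "generate_facility",
    "generate_flashdump",
    "EditRequest",
    "LedgerEntry",
    "InjectionLedger",
    "random_plan",
    "apply_modifications",
    "generate_pair",
    "CORRUPTION_MODES",
    "CORRUPTION_FINDING",
    "corrupt",
]

#: Number of device control units in the full facility.
FULL_DCU_COUNT = 177

#: Default number of parameters per device per setting (placeholder — real
#: per-device parameter counts are facility-internal).
DEFAULT_PARAMS_PER_SETTING = 10

#: Device taxonomy: class -> (device parameter names with (lo, hi, unit),
#: beam influences).  Replaceable as a whole; nothing else hard-codes it.
DEVICE_CLASSES: dict[str, dict] = {
    "dipole": {
        "params": {"magnet_current": (10.0, 900.0, "A"),
                   "coil_temperature": (20.0, 45.0, "degC")},
        "influences": ("energy", "position"),
    },
    "quadrupole": {
        "params": {"gradient": (0.5, 25.0, "T/m"),
                   "magnet_current": (5.0, 400.0, "A")},
        "influences": ("focus",),
    },
    "rf_cavity": {
        "params": {"rf_amplitude": (0.1, 12.0, "kV"),
                   "rf_phase": (-180.0, 180.0, "deg")},
        "influences": ("energy", "intensity"),
    },
    "scanner_magnet": {
        "params": {"deflection_current": (-50.0, 50.0, "A"),
                   "slew_rate": (1.0, 200.0, "A/ms")},
        "influences": ("position",),
    },
    "beam_monitor": {
        "params": {"gain": (1.0, 1000.0, None),
                   "threshold": (0.001, 1.0, "V")},
        "influences": ("intensity", "position"),
    },
    "steerer": {
        "params": {"kick_current": (-20.0, 20.0, "A")},
        "influences": ("position",),
    },
    "collimator": {
        "params": {"aperture": (2.0, 120.0, "mm"),
                   "jaw_offset": (-10.0, 10.0, "mm")},
        "influences": ("focus", "intensity"),
    },
}

_ROOM_SUBSETS = (("H1",), ("H2",), ("G1",), ("H1", "H2"), ("H1", "H2", "G1"))
_ROOM_WEIGHTS = (2, 2, 2, 3, 4)

_EPOCH = datetime(2025, 6, 1, 8, 0, 0, tzinfo=timezone.utc)


@dataclass
class FacilityModel:
    """A fully specified synthetic facility: inventory, rooms, grids, KB."""

    facility_id: str
    dcu_inventory: list[tuple[str, str, str]]  # (dcu_id, device_name, class)
    rooms: tuple[TreatmentRoom, ...]
    grids: dict[str, BeamParameterGrid]
    kb: KnowledgeBase
    scale: float = 1.0
    params_per_setting: int = DEFAULT_PARAMS_PER_SETTING

    @property
    def dcu_ids(self) -> list[str]:
        return [d[0] for d in self.dcu_inventory]

    def gantry_dcu_ids(self) -> set[str]:
        """Devices serving only the gantry room; they carry angle nodes."""
        gantry_rooms = {r.room_id for r in self.rooms
                        if r.beamline_type == "gantry"}
        return {dcu_id for dcu_id, e in self.kb.entries.items()
                if e.affected_rooms <= gantry_rooms}


def _scaled_axis(axis: AxisSpec, scale: float) -> AxisSpec:
    return AxisSpec(max(1, math.ceil(scale * axis.step_count)), axis.min, axis.max)


def _scaled_grid(grid: BeamParameterGrid, scale: float) -> BeamParameterGrid:
    return BeamParameterGrid(
        species=grid.species,
        energy=_scaled_axis(grid.energy, scale),
        focus=_scaled_axis(grid.focus, scale),
        intensity=_scaled_axis(grid.intensity, scale),
        gantry=GantrySpec(grid.gantry.resolution,
                          max(1, math.ceil(scale * grid.gantry.interpolation_step_count))),
    )


def generate_facility(seed: int, scale: float = 1.0) -> FacilityModel:
    """Generate a deterministic facility model.

    ``scale`` in (0, 1] shrinks the DCU inventory (ceil of scale × 177) and
    all grid step counts proportionally, never below one step; scale 1
    reproduces the full facility: 177 DCUs, the standard treatment grids and
    the 2-horizontal + 1-gantry room topology.
    """
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    rng = random.Random(f"facility:{seed}:{scale}")
    n = math.ceil(scale * FULL_DCU_COUNT)
    facility_id = f"SYN-{seed:08d}"
    classes = list(DEVICE_CLASSES)
    inventory: list[tuple[str, str, str]] = []
    counters: dict[str, int] = {}
    for i in range(1, n + 1):
        cls = classes[(i - 1) % len(classes)]
        counters[cls] = counters.get(cls, 0) + 1
        inventory.append((f"DCU-{i:03d}", f"{cls}-{counters[cls]:02d}", cls))

    entries: dict[str, KBEntry] = {}
    for dcu_id, name, cls in inventory:
        rooms = rng.choices(_ROOM_SUBSETS, weights=_ROOM_WEIGHTS, k=1)[0]
        entries[dcu_id] = KBEntry(
            dcu_id, name,
            influences=frozenset(DEVICE_CLASSES[cls]["influences"]),
            affected_rooms=frozenset(rooms))
    # topology guarantee: at least one gantry-only device so the angle-node
    # dimension is always exercised
    if not any(e.affected_rooms == {"G1"} for e in entries.values()):
        last_id, last_name, _ = inventory[-1]
        entries[last_id] = replace(entries[last_id],
                                   affected_rooms=frozenset({"G1"}))

    grids = {name: _scaled_grid(g, scale) for name, g in default_grids().items()}
    kb = KnowledgeBase(entries, version=f"kb-{seed}.{len(entries)}",
                       facility_id=facility_id)
    return FacilityModel(facility_id=facility_id, dcu_inventory=inventory,
                         rooms=DEFAULT_ROOMS, grids=grids, kb=kb, scale=scale)


# ---------------------------------------------------------------------------
# Dump generation

def _setting_keys(model: FacilityModel, dcu_id: str) -> list[SettingKey]:
    gantry = dcu_id in model.gantry_dcu_ids()
    keys: list[SettingKey] = []
    for sp_name in sorted(model.grids):
        g = model.grids[sp_name]
        nodes = range(g.gantry.interpolation_step_count) if gantry else (None,)
        for e in range(g.energy.step_count):
            for f in range(g.focus.step_count):
                for i in range(g.intensity.step_count):
                    for node in nodes:
                        keys.append(SettingKey.make(sp_name, e, f, i, node))
    return keys


def generate_flashdump(model: FacilityModel, seed: int, timestamp: datetime,
                       dump_type: str = "flash") -> Flashdump:
    """Populate every device over the full MEFI grid with in-range values.

    Each setting carries the physical MEFI echo parameters (energy, focus,
    intensity — the grid step values; gantry devices additionally the angle
    of their node) plus class-specific device parameters drawn uniformly from
    their plausible ranges, padded to the model's parameters-per-setting
    count.  Deterministic per (model, seed).
    """
    records: list[DCURecord] = []
    for dcu_id, name, cls in model.dcu_inventory:
        rng = random.Random(f"dump:{seed}:{dcu_id}")
        spec = DEVICE_CLASSES[cls]
        rec = DCURecord(dcu_id, name, cls)
        for key in _setting_keys(model, dcu_id):
            g = model.grids[key.species]
            params: dict[str, ParameterValue] = {
                "energy": ParameterValue.from_number(
                    round(step_value(g, "energy", key.energy_index), 6), "MeV/u"),
                "focus": ParameterValue.from_number(
                    round(step_value(g, "focus", key.focus_index), 6), "mm"),
                "intensity": ParameterValue.from_number(
                    step_value(g, "intensity", key.intensity_index), "1/s"),
            }
            if key.node >= 0:
                params["gantry_angle"] = ParameterValue.from_number(
                    angle_nodes(g)[key.node], "deg")
            for pname, (lo, hi, unit) in spec["params"].items():
                params[pname] = ParameterValue.from_number(
                    round(rng.uniform(lo, hi), 6), unit)
            pad = 0
            while len(params) < model.params_per_setting:
                pad += 1
                params[f"aux_{pad:02d}"] = ParameterValue.from_number(
                    round(rng.uniform(0.0, 1.0), 6))
            rec.settings[key] = params
        records.append(rec)
    header = FlashdumpHeader(dump_type=dump_type, export_timestamp=timestamp,
                             facility_id=model.facility_id)
    return Flashdump(header, records).seal()


# ---------------------------------------------------------------------------
# Modification plans and ledgers

@dataclass(frozen=True)
class EditRequest:
    """One requested edit; ``new_value=None`` asks for a seeded perturbation.

    ``out_of_range=True`` deliberately pushes a beam parameter outside its
    treatment-valid range (for negative tests).
    """

    dcu_id: str
    setting: SettingKey
    parameter_name: str
    new_value: Optional[str] = None
    unit: Optional[str] = None
    out_of_range: bool = False


@dataclass(frozen=True)
class LedgerEntry:
    dcu_id: str
    setting: SettingKey
    parameter_name: str
    old_value: str
    new_value: str


@dataclass
class InjectionLedger:
    """Exact record of the edits applied between a dump pair."""

    modifications: list[LedgerEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.modifications)

    def __iter__(self):
        return iter(self.modifications)

    @property
    def targets(self) -> set[tuple[str, SettingKey, str]]:
        return {(m.dcu_id, m.setting, m.parameter_name) for m in self}

    def as_change_set(self) -> set[tuple[str, str, str, str, str]]:
        """Hashable view for exact comparison with reported differences."""
        return {(m.dcu_id, str(m.setting), m.parameter_name, m.old_value,
                 m.new_value) for m in self}

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        return json.dumps([{"dcu_id": m.dcu_id, "setting": str(m.setting),
                            "parameter": m.parameter_name, "old": m.old_value,
                            "new": m.new_value} for m in self.modifications], **kw)


_GRID_PARAMS = ("energy", "focus", "intensity")


def random_plan(model: FacilityModel, dump: Flashdump, count: int,
                seed: int) -> list[EditRequest]:
    """Draw *count* distinct edit targets from a dump, deterministically."""
    rng = random.Random(f"plan:{seed}")
    targets: list[tuple[str, SettingKey, str]] = []
    for rec in dump.records:
        for key in sorted(rec.settings):
            for name in sorted(rec.settings[key]):
                targets.append((rec.dcu_id, key, name))
    if count > len(targets):
        raise ValueError(f"cannot draw {count} distinct targets from "
                         f"{len(targets)} parameters")
    chosen = rng.sample(targets, count)
    return [EditRequest(dcu_id, key, name) for dcu_id, key, name in chosen]


def _perturbed(model: Optional[FacilityModel], key: SettingKey, name: str,
               old: ParameterValue, rng: random.Random,
               out_of_range: bool) -> ParameterValue:
    if old.numeric_value is None:
        return ParameterValue(old.raw_text + "_edited", old.unit)
    grid = model.grids.get(key.species) if model is not None else None
    if name in _GRID_PARAMS and grid is not None:
        axis = grid.axis(name)
        if out_of_range:
            span = axis.max - axis.min
            return ParameterValue.from_number(round(axis.min - 0.1 * span, 6),
                                              old.unit)
        for _ in range(100):
            v = round(rng.uniform(axis.min, axis.max), 6)
            if v != old.numeric_value:
                return ParameterValue.from_number(v, old.unit)
        raise RuntimeError("could not draw a distinct in-range value")
    if name == "gantry_angle" and grid is not None:
        res = grid.gantry.resolution
        if out_of_range:
            return ParameterValue.from_number(360.0, old.unit)
        for _ in range(100):
            v = round(rng.randrange(0, int(360 / res)) * res, 10)
            if v != old.numeric_value:
                return ParameterValue.from_number(v, old.unit)
        raise RuntimeError("could not draw a distinct angle")
    factor = rng.uniform(1.02, 1.10) * rng.choice((-1.0, 1.0))
    new = old.numeric_value + abs(old.numeric_value) * factor + (
        rng.uniform(0.001, 0.01) if old.numeric_value == 0 else 0.0)
    return ParameterValue.from_number(round(new, 6), old.unit)


def apply_modifications(dump: Flashdump, plan: Sequence[EditRequest],
                        seed: int = 0, *, model: Optional[FacilityModel] = None,
                        timestamp: Optional[datetime] = None
                        ) -> tuple[Flashdump, InjectionLedger]:
    """Apply a plan of edits to a dump; return the new dump and the ledger.

    The modified dump gets a fresh (strictly later) timestamp and a resealed
    checksum.  Seeded perturbations keep beam parameters inside their
    physical range (so the resulting pair validates cleanly) unless the
    request explicitly asks for an out-of-range value.  Duplicate targets in
    one plan are rejected.
    """
    seen: set[tuple[str, SettingKey, str]] = set()
    for req in plan:
        t = (req.dcu_id, req.setting, req.parameter_name)
        if t in seen:
            raise UnresolvableTarget(f"duplicate edit target {t}")
        seen.add(t)
    new_dump = copy.deepcopy(dump)
    new_dump.header.export_timestamp = (
        timestamp if timestamp is not None
        else dump.header.export_timestamp + timedelta(hours=1))
    rng = random.Random(f"edits:{seed}")
    entries: list[LedgerEntry] = []
    rec_map = new_dump.record_map
    for req in plan:
        rec = rec_map.get(req.dcu_id)
        if rec is None:
            raise UnresolvableTarget(f"no DCU {req.dcu_id!r} in dump")
        params = rec.settings.get(req.setting)
        if params is None:
            raise UnresolvableTarget(
                f"no setting {req.setting} in DCU {req.dcu_id!r}")
        old = params.get(req.parameter_name)
        if old is None:
            raise UnresolvableTarget(
                f"no parameter {req.parameter_name!r} at "
                f"{req.dcu_id}/{req.setting}")
        if req.new_value is not None:
            new = ParameterValue(req.new_value,
                                 req.unit if req.unit is not None else old.unit)
        else:
            new = _perturbed(model, req.setting, req.parameter_name, old, rng,
                             req.out_of_range)
        params[req.parameter_name] = new
        entries.append(LedgerEntry(req.dcu_id, req.setting,
                                   req.parameter_name, old.canonical_text,
                                   new.canonical_text))
    new_dump.seal()
    return new_dump, InjectionLedger(entries)


def generate_pair(seed: int, scale: float = 0.05, n_edits: int = 3,
                  t0: datetime = _EPOCH
                  ) -> tuple[FacilityModel, Flashdump, Flashdump, InjectionLedger]:
    """Convenience: facility + base dump + edited dump + ledger, one seed."""
    model = generate_facility(seed, scale)
    base = generate_flashdump(model, seed, t0)
    plan = random_plan(model, base, n_edits, seed)
    current, ledger = apply_modifications(base, plan, seed, model=model)
    return model, base, current, ledger


# ---------------------------------------------------------------------------
# Corruption modes

CORRUPTION_MODES = ("bad_checksum", "schema_violation", "malformed_xml",
                    "ram_dump_type", "stale_timestamp", "identical_pair",
                    "unknown_dcu", "out_of_range_value")

#: Mode -> the single finding/error code it must trigger.  The first three
#: surface while reading; the rest are validation findings.
CORRUPTION_FINDING: dict[str, str] = {
    "bad_checksum": "checksum_mismatch",
    "schema_violation": "schema_violation",
    "malformed_xml": "malformed_xml",
    "ram_dump_type": "ram_dump_forbidden",
    "stale_timestamp": "outdated_dumps",
    "identical_pair": "identical_dumps",
    "unknown_dcu": "unknown_dcu",
    "out_of_range_value": "out_of_range",
}

Pair = tuple[Flashdump, Flashdump]


def _tamper_checksum(data: bytes) -> bytes:
    m = re.search(rb'payload_checksum="([0-9a-f]{64})"', data)
    digest = m.group(1)
    flipped = (b"1" if digest[:1] == b"0" else b"0") + digest[1:]
    return data[:m.start(1)] + flipped + data[m.end(1):]


def _drop_required_attribute(data: bytes) -> bytes:
    root = etree.fromstring(data)
    setting = root.find("body/dcu/setting")
    if setting is not None:
        del setting.attrib["species"]
    else:
        del root.find("header").attrib["dcu_count"]
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def corrupt(artifact: Union[Flashdump, Pair], mode: str,
            seed: int = 0) -> Union[bytes, tuple[bytes, bytes]]:
    """Produce a serialized artifact that triggers exactly one finding.

    Given a clean pair (last, current) the corrupted pair is returned as XML
    bytes; ``identical_pair`` and ``stale_timestamp`` require a pair, the
    other modes also accept a single dump (returning single-dump bytes).
    Each mode maps to exactly one read error or validation finding code
    (:data:`CORRUPTION_FINDING`).
    """
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}")
    is_pair = isinstance(artifact, tuple)
    if mode in ("identical_pair", "stale_timestamp") and not is_pair:
        raise InapplicableCorruption(f"{mode} requires a dump pair")
    last, current = artifact if is_pair else (None, artifact)
    current = copy.deepcopy(current)

    if mode == "stale_timestamp":
        current.header.export_timestamp = last.header.export_timestamp
    elif mode == "identical_pair":
        current = copy.deepcopy(last)
        current.header.export_timestamp += timedelta(hours=1)
    elif mode == "ram_dump_type":
        current.header.dump_type = "ram"
    elif mode == "unknown_dcu":
        donor = copy.deepcopy(current.records[0])
        donor.dcu_id = "DCU-GHOST"
        donor.device_name = "ghost-device"
        current.records.append(donor)
    elif mode == "out_of_range_value":
        rec = current.records[0]
        key = sorted(rec.settings)[0]
        rec.settings[key]["energy"] = ParameterValue.from_number(1.0, "MeV/u")

    data = write_flashdump(current)
    if mode == "bad_checksum":
        data = _tamper_checksum(data)
    elif mode == "schema_violation":
        data = _drop_required_attribute(data)
    elif mode == "malformed_xml":
        data = data[:-20]

    if is_pair:
        return write_flashdump(copy.deepcopy(last)), data
    return data
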