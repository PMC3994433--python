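"""Knowledge base and QA-checklist derivation.

Every beamline device perturbs a known subset of beam properties — its *beam
influence*: energy, focus, intensity and/or position.  The knowledge base is
a curated, version-controlled table mapping each device control unit to its
influences and to the treatment rooms its changes affect.  Given the
differences between two exports, the checklist engine proposes, per room, the
QA procedures (one per influence) that must be carried out and passed before
clinical operation resumes.

The engine is fail-safe by construction: a non-empty difference set can never
yield "no QA required", and a differenced device that cannot be resolved in
the knowledge base (reachable only when matching findings were deliberately
ignored) escalates to full QA — every procedure in every room.
"""

from __future__ import annotations

import fnmatch
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from .comparison import DifferenceSet, Difference
from .errors import ChecklistContractError, InvalidPattern, KBLoadError
from .facility import DEFAULT_ROOMS, TreatmentRoom
from .validation import ValidationReport

__all__ = [
    "BEAM_INFLUENCES",
    "KBEntry",
    "KnowledgeBase",
    "load_kb",
    "QAItem",
    "QAChecklist",
    "derive_checklist",
    "apply_output_filter",
    "render_report",
    "RAM_DEVIATION_BANNER",
]

#: Closed set of beam influences; each maps 1:1 to a QA procedure.
BEAM_INFLUENCES: tuple[str, ...] = ("energy", "focus", "intensity", "position")

#: QA procedure names, keyed by influence.
QA_PROCEDURES: dict[str, str] = {
    "energy": "beam energy check",
    "focus": "beam focus check",
    "intensity": "beam intensity check",
    "position": "beam position check",
}


@dataclass(frozen=True)
class KBEntry:
    """Knowledge-base record of one device control unit."""

    dcu_id: str
    device_name: str
    influences: frozenset[str]
    affected_rooms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.influences:
            raise ValueError(f"{self.dcu_id}: empty influence set")
        if not self.affected_rooms:
            raise ValueError(f"{self.dcu_id}: empty room set")


@dataclass
class KnowledgeBase:
    """All KB entries plus provenance (version, facility id)."""

    entries: dict[str, KBEntry]
    version: str
    facility_id: str

    def __len__(self) -> int:
        return len(self.entries)

    def write(self, sink: Union[str, Path, TextIO]) -> str:
        """Serialize to the tabular text format read by :func:`load_kb`."""
        lines = [
            "#%flashdiff-kb 1",
            f"#%version: {self.version}",
            f"#%facility_id: {self.facility_id}",
            "# dcu_id\tdevice_name\tinfluences\taffected_rooms",
        ]
        for dcu_id in sorted(self.entries):
            e = self.entries[dcu_id]
            lines.append("\t".join((
                e.dcu_id, e.device_name,
                ",".join(sorted(e.influences)),
                ",".join(sorted(e.affected_rooms)))))
        text = "\n".join(lines) + "\n"
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text, encoding="utf-8")
        else:
            sink.write(text)
        return text


def load_kb(source: Union[str, Path, TextIO],
            rooms: Sequence[TreatmentRoom] = DEFAULT_ROOMS,
            influences: Sequence[str] = BEAM_INFLUENCES) -> KnowledgeBase:
    """Load and fully check a knowledge-base file.

    The format is a plain tab-separated table (reviewable and diffable under
    version control, which is the mitigation for incorrect device entries):
    ``#%`` directives carry version and facility id, ``#`` lines are
    comments, data lines are ``dcu_id  device_name  influences  rooms`` with
    comma-separated lists.  Every invariant is checked at load time; each
    violation raises a distinct :class:`KBLoadError` naming the offending
    entry.
    """
    if isinstance(source, (str, Path)):
        try:
            text = Path(source).read_text(encoding="utf-8")
        except OSError as exc:
            raise KBLoadError("bad_format", f"cannot read {source}: {exc}")
    else:
        text = source.read()

    room_ids = {r.room_id for r in rooms}
    known_influences = set(influences)
    version = ""
    facility_id = ""
    entries: dict[str, KBEntry] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#%"):
            m = re.match(r"#%(\w+):\s*(.*)$", line)
            if m:
                if m.group(1) == "version":
                    version = m.group(2).strip()
                elif m.group(1) == "facility_id":
                    facility_id = m.group(2).strip()
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise KBLoadError(
                "bad_format",
                f"line {lineno}: expected 4 tab-separated fields, got "
                f"{len(fields)}")
        dcu_id, device_name, infl_text, rooms_text = (f.strip() for f in fields)
        if dcu_id in entries:
            raise KBLoadError("duplicate_dcu",
                              f"line {lineno}: duplicate dcu_id {dcu_id!r}",
                              entry=dcu_id)
        infl = {t.strip() for t in infl_text.split(",") if t.strip()}
        if not infl:
            raise KBLoadError("empty_influences",
                              f"line {lineno}: {dcu_id!r} has no influences",
                              entry=dcu_id)
        for token in sorted(infl):
            if token not in known_influences:
                raise KBLoadError(
                    "unknown_influence",
                    f"line {lineno}: {dcu_id!r} has unknown influence "
                    f"{token!r}", entry=dcu_id)
        affected = {t.strip() for t in rooms_text.split(",") if t.strip()}
        for room in sorted(affected):
            if room not in room_ids:
                raise KBLoadError(
                    "unknown_room",
                    f"line {lineno}: {dcu_id!r} affects unknown room "
                    f"{room!r}", entry=dcu_id)
        try:
            entries[dcu_id] = KBEntry(dcu_id, device_name, frozenset(infl),
                                      frozenset(affected))
        except ValueError as exc:
            raise KBLoadError("bad_format", f"line {lineno}: {exc}",
                              entry=dcu_id)
    return KnowledgeBase(entries, version=version, facility_id=facility_id)


# ---------------------------------------------------------------------------
# Checklist

@dataclass
class QAItem:
    """One required QA procedure in one room, with traceability."""

    room_id: str
    influence: str
    triggering_differences: list[Difference]
    escalation: bool = False

    @property
    def procedure(self) -> str:
        return QA_PROCEDURES.get(self.influence, f"{self.influence} check")

    def to_dict(self) -> dict:
        return {"room": self.room_id, "influence": self.influence,
                "procedure": self.procedure, "escalation": self.escalation,
                "triggered_by": [d.to_dict() for d in self.triggering_differences]}


@dataclass
class QAChecklist:
    """Per-room QA items plus the overall verdict."""

    items: list[QAItem] = field(default_factory=list)
    unresolved_dcus: set[str] = field(default_factory=set)

    @property
    def verdict(self) -> str:
        if self.unresolved_dcus:
            return "escalate_full_qa"
        return "qa_required" if self.items else "no_qa_required"

    def rooms(self) -> list[str]:
        return sorted({i.room_id for i in self.items})

    def items_by_room(self) -> dict[str, list[QAItem]]:
        out: dict[str, list[QAItem]] = {}
        for item in self.items:
            out.setdefault(item.room_id, []).append(item)
        for room in out:
            out[room].sort(key=lambda i: i.influence)
        return dict(sorted(out.items()))

    @property
    def required_pairs(self) -> set[tuple[str, str]]:
        """Set of (room_id, influence) pairs the checklist requires."""
        return {(i.room_id, i.influence) for i in self.items}

    def to_dict(self) -> dict:
        return {"verdict": self.verdict,
                "unresolved_dcus": sorted(self.unresolved_dcus),
                "items": [i.to_dict() for room, its in self.items_by_room().items()
                          for i in its]}


def derive_checklist(diffs: DifferenceSet, kb: KnowledgeBase,
                     rooms: Sequence[TreatmentRoom] = DEFAULT_ROOMS,
                     *, checklist_permitted: bool = True) -> QAChecklist:
    """Map detected differences to required QA procedures per room.

    For every differenced device with a KB entry, each of its influences is
    required in each of its affected rooms; structural differences (a device
    appearing or disappearing) trigger all of the device's influences.  Items
    are aggregated per (room, influence) pair and carry every triggering
    difference for traceability.  A differenced device without a KB entry
    escalates to full QA: every influence in every room of the facility.

    Calling this with ``checklist_permitted=False`` (validation forbade a
    checklist) is a contract violation and raises.
    """
    if not checklist_permitted:
        raise ChecklistContractError(
            "checklist derivation requested although validation did not pass")
    by_pair: dict[tuple[str, str], list[Difference]] = {}
    unresolved: set[str] = set()
    escalation_trigger: list[Difference] = []
    for diff in diffs:
        entry = kb.entries.get(diff.dcu_id)
        if entry is None:
            unresolved.add(diff.dcu_id)
            escalation_trigger.append(diff)
            continue
        for influence in sorted(entry.influences):
            for room in sorted(entry.affected_rooms):
                by_pair.setdefault((room, influence), []).append(diff)
    items = [QAItem(room, influence, trig)
             for (room, influence), trig in sorted(by_pair.items())]
    if unresolved:
        # fail-safe escalation: recommend everything everywhere
        all_pairs = {(r.room_id, infl) for r in rooms for infl in BEAM_INFLUENCES}
        covered = {(i.room_id, i.influence) for i in items}
        for room, influence in sorted(all_pairs - covered):
            items.append(QAItem(room, influence, list(escalation_trigger),
                                escalation=True))
        for item in items:
            item.escalation = True
        items.sort(key=lambda i: (i.room_id, i.influence))
    return QAChecklist(items=items, unresolved_dcus=unresolved)


# ---------------------------------------------------------------------------
# Output filter

def apply_output_filter(diffs: DifferenceSet,
                        patterns: Sequence[str]) -> DifferenceSet:
    """Restrict the *printed* difference listing to matching entries.

    Patterns are shell globs matched against ``dcu_id`` and
    ``dcu_id/parameter_name``.  An empty pattern list leaves the set
    untouched.  Filters only ever affect the display: the QA checklist is
    always derived from the unfiltered set, so a misconfigured filter cannot
    hide a required procedure.
    """
    for p in patterns:
        if not p or not p.strip():
            raise InvalidPattern("empty filter pattern")
    if not patterns:
        return diffs
    kept = []
    for d in diffs:
        subjects = [d.dcu_id]
        if d.parameter_name:
            subjects.append(f"{d.dcu_id}/{d.parameter_name}")
        if any(fnmatch.fnmatchcase(s, p) for s in subjects for p in patterns):
            kept.append(d)
    return DifferenceSet(kept)


# ---------------------------------------------------------------------------
# Result print

RAM_DEVIATION_BANNER = (
    "*** DEVIATION FROM INTENDED USE: RAM export comparison enabled — "
    "results are NOT valid for clinical release ***")


@dataclass
class RunContext:
    """Provenance recorded on every result print."""

    tool_version: str
    kb_version: str = ""
    allow_ram: bool = False
    ignore: bool = False
    filters: Sequence[str] = ()
    last_label: str = "last"
    current_label: str = "current"


def _dump_meta(dump) -> dict:
    from .dumpio import format_timestamp
    return {"dump_type": dump.header.dump_type,
            "export_timestamp": format_timestamp(dump.header.export_timestamp),
            "facility_id": dump.header.facility_id,
            "payload_checksum": dump.header.payload_checksum,
            "dcu_count": dump.header.dcu_count}


def render_report(checklist: Optional[QAChecklist],
                  diffs: Optional[DifferenceSet],
                  validation: ValidationReport,
                  context: RunContext,
                  last=None, current=None,
                  display_diffs: Optional[DifferenceSet] = None,
                  fmt: str = "text") -> str:
    """Render the result print in plain text or JSON (identical content).

    ``checklist=None`` means the run was diff-only or aborted: the print then
    carries an explicit statement that no checklist is issued.  When the RAM
    flag was used, a deviation banner heads the report in every format.
    ``display_diffs`` is the (possibly filtered) listing; traceability inside
    the checklist always refers to the unfiltered set.
    """
    if fmt not in ("text", "json"):
        raise ValueError(f"unknown report format {fmt!r}")
    shown = display_diffs if display_diffs is not None else diffs

    if fmt == "json":
        doc = {
            "banner": RAM_DEVIATION_BANNER if context.allow_ram else None,
            "tool_version": context.tool_version,
            "kb_version": context.kb_version,
            "options": {"ignore": context.ignore,
                        "allow_ram": context.allow_ram,
                        "filters": list(context.filters)},
            "dumps": {
                "last": _dump_meta(last) if last is not None else None,
                "current": _dump_meta(current) if current is not None else None,
            },
            "validation": {
                "passed": validation.passed,
                "findings": [{"code": f.code, "severity": f.severity,
                              "ignorable": f.ignorable, "location": f.location,
                              "message": f.message}
                             for f in validation.findings],
            },
            "differences": shown.to_dict() if shown is not None else None,
            "checklist": checklist.to_dict() if checklist is not None else None,
            "checklist_suppressed": checklist is None,
        }
        return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"

    lines: list[str] = []
    if context.allow_ram:
        lines.append(RAM_DEVIATION_BANNER)
        lines.append("")
    lines.append("FLASHDUMP COMPARISON RESULT")
    lines.append("=" * 60)
    lines.append(f"tool version:       {context.tool_version}")
    lines.append(f"knowledge base:     version {context.kb_version or '?'}")
    for label, dump in (("last", last), ("current", current)):
        if dump is None:
            continue
        m = _dump_meta(dump)
        lines.append(f"{label} dump:")
        lines.append(f"  type {m['dump_type']}  exported {m['export_timestamp']}  "
                     f"facility {m['facility_id']}")
        lines.append(f"  checksum {m['payload_checksum']}")
    if context.filters:
        lines.append(f"output filters:     {', '.join(context.filters)} "
                     "(display only; checklist unaffected)")
    lines.append("")
    lines.append(f"VALIDATION: {'passed' if validation.passed else 'FAILED'}")
    for f in validation.findings:
        lines.append(f"  {f}")
    if shown is not None:
        lines.append("")
        lines.append(f"DIFFERENCES ({len(shown)} shown)")
        for d in shown:
            lines.append(f"  {d}")
    if checklist is None:
        lines.append("")
        lines.append("NO QA CHECKLIST ISSUED: validation did not pass; the "
                     "listing above is informational only and does not "
                     "authorize clinical release.")
    else:
        lines.append("")
        lines.append(f"QA CHECKLIST — verdict: {checklist.verdict}")
        if checklist.verdict == "no_qa_required":
            lines.append("  No QA required: no differences were detected.")
        if checklist.unresolved_dcus:
            lines.append("  ESCALATION: differenced device(s) without "
                         "knowledge-base entry: "
                         + ", ".join(sorted(checklist.unresolved_dcus)))
        for room, items in checklist.items_by_room().items():
            lines.append(f"  room {room}:")
            for item in items:
                trig = ", ".join(sorted({d.dcu_id for d in
                                         item.triggering_differences}))
                mark = " [escalation]" if item.escalation else ""
                lines.append(f"    - {item.procedure}{mark} (triggered by {trig})")
    lines.append("")
    return "\n".join(lines)
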