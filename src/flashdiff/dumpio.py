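"""Flashdump XML dialect: parsing, canonical serialization and checksums.

The facility's accelerator control system can export the MEFI parameter
libraries of all device control units as one XML document ("flashdump").
This module defines a self-contained dialect for such exports — a header
carrying integrity metadata (dump type, UTC timestamp, payload checksum, DCU
count) and one ``dcu`` element per control unit — together with a bundled XSD,
a canonical writer and a layered reader.

Canonical form: DCU records sorted by id, settings sorted by (species, MEFI
indices, angle node), parameters sorted by name, numeric values rendered in
shortest round-trip notation.  The payload checksum is SHA-256 over a
canonical line-oriented serialization of the parsed body, so it is invariant
under XML reformatting (whitespace, attribute order, numeric formatting) and
sensitive to every semantic change.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import BinaryIO, Iterable, Iterator, Mapping, Optional, Union

from lxml import etree

from .errors import MalformedXML, NotProcessable, SchemaViolation
from .facility import MEFIKey

__all__ = [
    "FORMAT_VERSION",
    "SettingKey",
    "ParameterValue",
    "DCURecord",
    "FlashdumpHeader",
    "Flashdump",
    "read_flashdump",
    "write_flashdump",
    "compute_checksum",
    "parse_timestamp",
    "format_timestamp",
]

FORMAT_VERSION = "1.0"

_TS_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


def parse_timestamp(text: str) -> datetime:
    """Parse an ISO-8601 UTC instant with trailing Z."""
    try:
        return datetime.strptime(text, _TS_FORMAT).replace(tzinfo=timezone.utc)
    except ValueError as exc:
        raise SchemaViolation(f"bad timestamp {text!r}: {exc}") from None


def format_timestamp(ts: datetime) -> str:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc).strftime(_TS_FORMAT)


@dataclass(frozen=True, order=True)
class SettingKey:
    """Key of one device parameter set: MEFI indices plus optional angle node.

    Gantry-room devices store one parameter set per (MEFI, angle node) pair;
    for all other devices ``node`` is ``None``.  Ordering treats a missing
    node as -1 so keys sort deterministically.
    """

    species: str
    energy_index: int
    focus_index: int
    intensity_index: int
    node: int = -1  # -1 = no angle-node dimension

    @classmethod
    def make(cls, species: str, e: int, f: int, i: int,
             node: Optional[int] = None) -> "SettingKey":
        return cls(species, e, f, i, -1 if node is None else node)

    @property
    def mefi(self) -> MEFIKey:
        return MEFIKey(self.species, self.energy_index, self.focus_index,
                       self.intensity_index)

    @property
    def angle_node(self) -> Optional[int]:
        return None if self.node < 0 else self.node

    def __str__(self) -> str:
        base = (f"{self.species}/e{self.energy_index}"
                f"/f{self.focus_index}/i{self.intensity_index}")
        return base if self.node < 0 else f"{base}/n{self.node}"


def _parse_numeric(text: str) -> Optional[float]:
    try:
        v = float(text)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


@dataclass(frozen=True)
class ParameterValue:
    """One device parameter value as serialized, with its numeric reading.

    ``numeric_value`` is set iff ``raw_text`` parses as a finite decimal.
    Equality is numeric when both sides are numeric (so "1.0" == "1.00"),
    textual otherwise.
    """

    raw_text: str
    unit: Optional[str] = None
    numeric_value: Optional[float] = field(init=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "numeric_value", _parse_numeric(self.raw_text))

    @classmethod
    def from_number(cls, value: float, unit: Optional[str] = None) -> "ParameterValue":
        return cls(repr(float(value)), unit)

    @property
    def canonical_text(self) -> str:
        """Shortest round-trip text for numeric values, raw text otherwise."""
        if self.numeric_value is not None:
            return repr(self.numeric_value)
        return self.raw_text

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterValue):
            return NotImplemented
        if self.numeric_value is not None and other.numeric_value is not None:
            return (self.numeric_value == other.numeric_value
                    and self.unit == other.unit)
        return self.raw_text == other.raw_text and self.unit == other.unit

    def __hash__(self) -> int:
        return hash((self.canonical_text, self.unit))


Settings = Mapping[SettingKey, Mapping[str, ParameterValue]]


@dataclass
class DCURecord:
    """Parameter library of one device control unit."""

    dcu_id: str
    device_name: str
    device_class: str
    settings: dict[SettingKey, dict[str, ParameterValue]] = field(default_factory=dict)

    def sorted_settings(self) -> list[tuple[SettingKey, dict[str, ParameterValue]]]:
        return sorted(self.settings.items(), key=lambda kv: kv[0])


@dataclass
class FlashdumpHeader:
    dump_type: str  # "flash" | "ram"
    export_timestamp: datetime
    facility_id: str
    format_version: str = FORMAT_VERSION
    payload_checksum: str = ""
    dcu_count: int = 0


@dataclass
class Flashdump:
    """A parsed flashdump: header plus DCU records in canonical id order."""

    header: FlashdumpHeader
    records: list[DCURecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records.sort(key=lambda r: r.dcu_id)

    @property
    def record_map(self) -> dict[str, DCURecord]:
        return {r.dcu_id: r for r in self.records}

    @property
    def dcu_ids(self) -> list[str]:
        return [r.dcu_id for r in self.records]

    def seal(self) -> "Flashdump":
        """Recompute dcu_count and payload_checksum from the body."""
        self.records.sort(key=lambda r: r.dcu_id)
        self.header.dcu_count = len(self.records)
        self.header.payload_checksum = compute_checksum(self.records)
        return self


# ---------------------------------------------------------------------------
# Canonical body serialization + checksum

def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("|", "\\|").replace("\n", "\\n")


def canonical_body_lines(records: Iterable[DCURecord]) -> Iterator[str]:
    """Line-oriented canonical serialization of the dump body.

    One ``dcu|...`` line per record, one ``s|...`` line per setting and one
    ``p|...`` line per parameter, all in canonical order, with ``|``,
    backslash and newline escaped inside fields.  This is the checksum input.
    """
    for rec in sorted(records, key=lambda r: r.dcu_id):
        yield "|".join(("dcu", _escape(rec.dcu_id), _escape(rec.device_name),
                        _escape(rec.device_class)))
        for key, params in sorted(rec.settings.items(), key=lambda kv: kv[0]):
            yield "|".join(("s", _escape(key.species), str(key.energy_index),
                            str(key.focus_index), str(key.intensity_index),
                            str(key.node)))
            for name in sorted(params):
                pv = params[name]
                yield "|".join(("p", _escape(name), _escape(pv.canonical_text),
                                _escape(pv.unit) if pv.unit is not None else "-"))


def compute_checksum(records: Iterable[DCURecord]) -> str:
    """SHA-256 hex digest of the canonical body serialization."""
    h = hashlib.sha256()
    for line in canonical_body_lines(records):
        h.update(line.encode("utf-8"))
        h.update(b"\n")
    return h.hexdigest()


# ---------------------------------------------------------------------------
# XSD

def _load_schema() -> etree.XMLSchema:
    with resources.files(__package__).joinpath("schema/flashdump.xsd").open("rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


_SCHEMA: Optional[etree.XMLSchema] = None


def _schema() -> etree.XMLSchema:
    global _SCHEMA
    if _SCHEMA is None:
        _SCHEMA = _load_schema()
    return _SCHEMA


# ---------------------------------------------------------------------------
# Writer

def write_flashdump(dump: Flashdump,
                    sink: Union[str, Path, BinaryIO, None] = None) -> bytes:
    """Serialize a dump to canonical XML bytes, resealing the header.

    The DCU count and payload checksum are recomputed and embedded, so the
    written document is always internally consistent.  Output is
    deterministic: the same dump (regardless of record order on input)
    serializes to byte-identical XML.
    """
    dump.seal()
    root = etree.Element("flashdump", format_version=dump.header.format_version)
    etree.SubElement(
        root, "header",
        dump_type=dump.header.dump_type,
        export_timestamp=format_timestamp(dump.header.export_timestamp),
        facility_id=dump.header.facility_id,
        dcu_count=str(dump.header.dcu_count),
        payload_checksum=dump.header.payload_checksum,
    )
    body = etree.SubElement(root, "body")
    for rec in dump.records:
        dcu_el = etree.SubElement(body, "dcu", id=rec.dcu_id,
                                  name=rec.device_name)
        dcu_el.set("class", rec.device_class)
        for key, params in rec.sorted_settings():
            s_el = etree.SubElement(dcu_el, "setting", species=key.species,
                                    e=str(key.energy_index),
                                    f=str(key.focus_index),
                                    i=str(key.intensity_index))
            if key.node >= 0:
                s_el.set("node", str(key.node))
            for name in sorted(params):
                pv = params[name]
                p_el = etree.SubElement(s_el, "param", name=name,
                                        value=pv.canonical_text)
                if pv.unit is not None:
                    p_el.set("unit", pv.unit)
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_bytes(data)
        else:
            sink.write(data)
    return data


# ---------------------------------------------------------------------------
# Reader

def read_flashdump(source: Union[str, Path, bytes, BinaryIO]) -> Flashdump:
    """Parse and schema-validate a flashdump.

    Failure layers are distinguished: :class:`NotProcessable` (missing or
    unreadable input), :class:`MalformedXML` (not well-formed) and
    :class:`SchemaViolation` (well-formed but dialect-invalid, with the
    offending element path).  Integrity of declared count/checksum against
    the body is *not* checked here — that is a validation-stage concern.
    """
    if isinstance(source, bytes):
        data = source
    elif isinstance(source, (str, Path)):
        try:
            data = Path(source).read_bytes()
        except OSError as exc:
            raise NotProcessable(f"cannot read {source}: {exc}") from None
    else:
        try:
            data = source.read()
        except OSError as exc:
            raise NotProcessable(f"cannot read stream: {exc}") from None

    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise MalformedXML(f"not well-formed XML: {exc}") from None

    schema = _schema()
    if not schema.validate(root):
        err = schema.error_log[0]
        raise SchemaViolation(err.message, path=err.path or "")

    h_el = root.find("header")
    header = FlashdumpHeader(
        dump_type=h_el.get("dump_type"),
        export_timestamp=parse_timestamp(h_el.get("export_timestamp")),
        facility_id=h_el.get("facility_id"),
        format_version=root.get("format_version"),
        payload_checksum=h_el.get("payload_checksum"),
        dcu_count=int(h_el.get("dcu_count")),
    )
    records: list[DCURecord] = []
    seen_ids: set[str] = set()
    for dcu_el in root.find("body"):
        dcu_id = dcu_el.get("id")
        if dcu_id in seen_ids:
            raise SchemaViolation(f"duplicate dcu id {dcu_id!r}",
                                  path=f"/flashdump/body/dcu[@id='{dcu_id}']")
        seen_ids.add(dcu_id)
        rec = DCURecord(dcu_id, dcu_el.get("name"), dcu_el.get("class"))
        for s_el in dcu_el:
            node = s_el.get("node")
            key = SettingKey.make(s_el.get("species"), int(s_el.get("e")),
                                  int(s_el.get("f")), int(s_el.get("i")),
                                  None if node is None else int(node))
            if key in rec.settings:
                raise SchemaViolation(f"duplicate setting {key} in {dcu_id}",
                                      path=f"/flashdump/body/dcu[@id='{dcu_id}']")
            params: dict[str, ParameterValue] = {}
            for p_el in s_el:
                name = p_el.get("name")
                if name in params:
                    raise SchemaViolation(
                        f"duplicate parameter {name!r} in {dcu_id}/{key}",
                        path=f"/flashdump/body/dcu[@id='{dcu_id}']")
                params[name] = ParameterValue(p_el.get("value"), p_el.get("unit"))
            rec.settings[key] = params
        records.append(rec)
    return Flashdump(header, records)
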