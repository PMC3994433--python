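"""Pre-comparison validation of a flashdump pair.

Before two exports may be compared and turned into a QA checklist, a fixed
sequence of integrity checks runs: (1) header consistency (declared DCU count
and payload checksum against the body, matching facility ids); (2) dump type
— only flash-memory exports are compared unless the dedicated RAM flag is
set; (3) freshness — the current export must be strictly newer than the last,
and the two must not be identical; (4) physical range of every beam-parameter
value and MEFI index against the species grids; (5) bidirectional matching of
dump DCU ids against the knowledge base.

No check raises: every outcome is a :class:`Finding` with a stable code from
the shipped catalogue.  The worst-case hazard of the tool is a false negative
— a result print claiming no QA is required while a treatment-relevant
parameter changed — so a QA checklist is only ever permitted when validation
passed completely: the ignore flag can downgrade a run to a diff-only print,
never re-enable the checklist, and integrity-defeating findings (checksum,
dump type, ordering) cannot be ignored at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Optional

from .dumpio import Flashdump, compute_checksum
from .facility import BeamParameterGrid, default_grids, in_range

__all__ = [
    "FINDING_CATALOG",
    "Finding",
    "ValidationReport",
    "ValidationOptions",
    "Disposition",
    "validate_pair",
    "effective_disposition",
]


def _load_catalog() -> dict:
    with resources.files(__package__).joinpath("data/finding_codes.json").open("rb") as fh:
        return json.load(fh)["codes"]


#: Closed catalogue of finding codes; the JSON file shipped with the package
#: is the machine-readable interface for downstream tooling.
FINDING_CATALOG: dict[str, dict] = _load_catalog()

#: Beam-parameter names checked against the grid axes in stage 4.
GRID_QUANTITY_PARAMS = ("energy", "focus", "intensity", "gantry_angle")


@dataclass(frozen=True)
class Finding:
    """One validation outcome with a stable, catalogued code."""

    code: str
    message: str
    location: str = ""  # dump / dcu_id / setting / parameter path

    def __post_init__(self) -> None:
        if self.code not in FINDING_CATALOG:
            raise ValueError(f"finding code {self.code!r} not in catalogue")

    @property
    def severity(self) -> str:
        return FINDING_CATALOG[self.code]["severity"]

    @property
    def ignorable(self) -> bool:
        return FINDING_CATALOG[self.code]["ignorable"]

    @property
    def fatal(self) -> bool:
        return self.severity == "fatal"

    def __str__(self) -> str:
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.severity.upper()} {self.code}{loc}: {self.message}"


@dataclass
class ValidationReport:
    """Ordered findings plus the derived pass/checklist verdicts.

    ``checklist_permitted`` is the executable fail-safe contract: it is true
    iff validation passed with no fatal finding, and can never be turned true
    by the ignore flag.
    """

    findings: list[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(f.fatal for f in self.findings)

    @property
    def checklist_permitted(self) -> bool:
        return self.passed

    @property
    def fatal_findings(self) -> list[Finding]:
        return [f for f in self.findings if f.fatal]


@dataclass(frozen=True)
class ValidationOptions:
    """Run options relevant to validation.

    ``grids`` maps species name to its beam-parameter grid; ``None`` selects
    the default facility grids.  ``allow_ram`` is the dedicated flag for
    comparing RAM exports; it is deliberately separate from ``ignore``.
    """

    ignore: bool = False
    allow_ram: bool = False
    grids: Optional[Mapping[str, BeamParameterGrid]] = None

    def grid_registry(self) -> Mapping[str, BeamParameterGrid]:
        return self.grids if self.grids is not None else default_grids()


class Disposition(str, Enum):
    """What the run may do after validation."""

    PROCEED_FULL = "proceed_full"          # compare + checklist
    PROCEED_DIFF_ONLY = "proceed_diff_only"  # compare, checklist suppressed
    ABORT = "abort"


def _check_headers(label: str, dump: Flashdump, out: list[Finding]) -> None:
    n = len(dump.records)
    if dump.header.dcu_count != n:
        out.append(Finding(
            "header_count_mismatch",
            f"header declares {dump.header.dcu_count} DCUs, body has {n}",
            location=label))
    actual = compute_checksum(dump.records)
    if dump.header.payload_checksum != actual:
        out.append(Finding(
            "checksum_mismatch",
            f"declared checksum {dump.header.payload_checksum[:12]}… does not "
            f"match recomputed {actual[:12]}…",
            location=label))


def _check_ranges(label: str, dump: Flashdump,
                  grids: Mapping[str, BeamParameterGrid],
                  out: list[Finding]) -> None:
    for rec in dump.records:
        for key, params in rec.sorted_settings():
            grid = grids.get(key.species)
            if grid is None:
                out.append(Finding(
                    "unknown_species",
                    f"species {key.species!r} not in grid registry",
                    location=f"{label}/{rec.dcu_id}/{key}"))
                continue
            try:
                key.mefi.validate_against(grid)
            except IndexError as exc:
                out.append(Finding("invalid_mefi_index", str(exc),
                                   location=f"{label}/{rec.dcu_id}/{key}"))
            if key.node >= grid.gantry.interpolation_step_count:
                out.append(Finding(
                    "invalid_mefi_index",
                    f"angle node {key.node} out of range "
                    f"[0, {grid.gantry.interpolation_step_count})",
                    location=f"{label}/{rec.dcu_id}/{key}"))
            for name in sorted(params):
                if name not in GRID_QUANTITY_PARAMS:
                    continue
                pv = params[name]
                if pv.numeric_value is None:
                    continue
                check = in_range(grid, name, pv.numeric_value)
                if not check:
                    out.append(Finding(
                        "out_of_range", check.reason,
                        location=f"{label}/{rec.dcu_id}/{key}/{name}"))


def validate_pair(last: Flashdump, current: Flashdump, kb,
                  options: Optional[ValidationOptions] = None) -> ValidationReport:
    """Run all pre-comparison checks on a parsed dump pair.

    ``kb`` is a loaded :class:`~flashdiff.qa.KnowledgeBase` (only its id set
    and facility id are consulted here).  Pure function: the same inputs
    always produce the same report, with findings in deterministic order
    (check stage, then dump, then location).
    """
    options = options or ValidationOptions()
    findings: list[Finding] = []

    # stage 1: header consistency + facility identity
    _check_headers("last", last, findings)
    _check_headers("current", current, findings)
    if last.header.facility_id != current.header.facility_id:
        findings.append(Finding(
            "facility_mismatch",
            f"last export is from {last.header.facility_id!r}, current from "
            f"{current.header.facility_id!r}", location="pair"))
    if kb is not None and kb.facility_id != current.header.facility_id:
        findings.append(Finding(
            "facility_mismatch",
            f"knowledge base is for {kb.facility_id!r}, dumps for "
            f"{current.header.facility_id!r}", location="kb"))

    # stage 2: dump type (flash-only by default)
    for label, dump in (("last", last), ("current", current)):
        if dump.header.dump_type != "flash" and not options.allow_ram:
            findings.append(Finding(
                "ram_dump_forbidden",
                f"{label} dump is a {dump.header.dump_type!r} export; RAM "
                "comparisons require the dedicated RAM flag",
                location=label))

    # stage 3: freshness and identity
    if current.header.export_timestamp <= last.header.export_timestamp:
        findings.append(Finding(
            "outdated_dumps",
            f"current export ({dumpts(current)}) is not strictly later than "
            f"last export ({dumpts(last)})", location="pair"))
    if (compute_checksum(last.records) == compute_checksum(current.records)):
        findings.append(Finding(
            "identical_dumps",
            "both dumps have identical payloads; nothing can have changed",
            location="pair"))

    # stage 4: physical ranges and index validity
    grids = options.grid_registry()
    _check_ranges("last", last, grids, findings)
    _check_ranges("current", current, grids, findings)

    # stage 5: DCU matching against the knowledge base, both directions
    if kb is not None:
        kb_ids = set(kb.entries)
        for label, dump in (("last", last), ("current", current)):
            dump_ids = set(dump.dcu_ids)
            for dcu_id in sorted(dump_ids - kb_ids):
                findings.append(Finding(
                    "unknown_dcu",
                    f"DCU {dcu_id!r} in {label} dump has no knowledge-base entry",
                    location=f"{label}/{dcu_id}"))
            for dcu_id in sorted(kb_ids - dump_ids):
                findings.append(Finding(
                    "missing_dcu",
                    f"DCU {dcu_id!r} from the knowledge base is absent from "
                    f"the {label} dump", location=f"{label}/{dcu_id}"))

    return ValidationReport(findings)


def dumpts(dump: Flashdump) -> str:
    from .dumpio import format_timestamp
    return format_timestamp(dump.header.export_timestamp)


def effective_disposition(report: ValidationReport,
                          options: Optional[ValidationOptions] = None) -> Disposition:
    """Decide how the run proceeds given the validation outcome.

    No fatal finding: full run.  Fatal but all-ignorable findings with the
    ignore flag set: comparison continues for research purposes, but only the
    differences are printed — never a checklist.  Anything else aborts.
    Adding findings can only ever push the disposition downward.
    """
    options = options or ValidationOptions()
    fatals = report.fatal_findings
    if not fatals:
        return Disposition.PROCEED_FULL
    if options.ignore and all(f.ignorable for f in fatals):
        return Disposition.PROCEED_DIFF_ONLY
    return Disposition.ABORT
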