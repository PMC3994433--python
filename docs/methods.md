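# Methods

## The facility model

The package models a dual-species ion-therapy facility whose beam settings
are discrete: every validated setting is a MEFI tuple (ion species, energy
step, focus step, intensity step) indexing into per-species parameter grids.
The default grids are the treatment-validated ranges of a representative
carbon/proton synchrotron facility:

| axis                | protons                 | carbon ions           |
|---------------------|-------------------------|-----------------------|
| energy              | 255 steps, 48–221 MeV/u | 255 steps, 88–430 MeV/u |
| focus (FWHM)        | 1 step, 8–32 mm         | 4 steps, 6–12 mm      |
| intensity           | 9 steps, 1e8–3e10 1/s   | 8 steps, 1e7–1e8 1/s  |
| gantry angle        | resolution 0.01°, 36 interpolation nodes (both species) |

The facility has 177 device control units (DCUs) and three treatment rooms:
two fixed horizontal beamlines (H1, H2) and one gantry room (G1).

Assumptions made where the public record is silent, fixed as package design
choices:

- **Step spacing is linear** from min to max inclusive (only step counts and
  ranges are published; real facilities use tabulated libraries).  A config
  override (`grids_from_config`) is the supported path to replace it.
- A **single-step axis returns its minimum** as the step value while the
  recorded range is the validity window (the proton focus axis has one step
  but an 8–32 mm window); consequently the endpoint identity
  `step_value(n−1) = max` holds only for axes with ≥ 2 steps.
- Energy/focus/intensity step tables are **facility-global**, not per-room.
- The **gantry angle is a per-setting device parameter** (validated as a
  0.01° multiple in [0°, 360°)), not a MEFI dimension; the 36 interpolation
  nodes appear as an extra angle-node index on the settings of gantry-room
  devices.
- Range acceptance is **closed on both ends** — the grids tabulate
  treatment-valid ranges, so the bounds themselves are valid settings.

## Flashdump dialect and integrity

The XML dialect (root `flashdump`, a `header` element, one `dcu` element per
control unit with `setting` and `param` children) is this package's own,
with a bundled XSD versioned through `format_version`; the real export
format is unpublished.  Canonical form: records sorted by DCU id, settings
by (species, MEFI indices, angle node), parameters by name, numeric values
in shortest round-trip notation, UTF-8, timestamps as ISO-8601 UTC instants
with trailing `Z`.

The payload checksum is **SHA-256 over a canonical line-oriented
serialization of the parsed body** (one escaped record per DCU, setting and
parameter), excluding the header.  Computing it from the parsed content
rather than raw bytes makes the digest invariant under XML reformatting
(whitespace, attribute order, `1.0` vs `1.00`) and sensitive to every
semantic change; one checksum covers the whole dump.  Real exports are on
the order of hundreds of megabytes; the reader keeps one parsed document in
memory, which is adequate for the synthetic scales used here (a streaming
reader would be the first change for production-size inputs).

Read failures are layered — unreadable input, not well-formed XML,
XSD-invalid — so operators can distinguish a transfer problem from a
corrupted export.

## Validation and dispositions

`validate_pair` runs five stages in fixed order: header consistency
(declared DCU count and checksum recomputed over the body, facility
identity), dump type, freshness/identity, physical ranges and MEFI/angle
index validity, and bidirectional DCU matching against the knowledge base.
Every outcome is a finding with a stable code from the shipped catalogue
(`data/finding_codes.json`); nothing raises.

Two findings classes exist.  *Ignorable* fatal findings (range violations,
count mismatches, matching mismatches, facility mismatches) may be bypassed
with the `--ignore` research flag, which downgrades the run to a diff-only
print — the checklist is suppressed, never computed.  *Non-ignorable*
findings (checksum mismatch, identical dumps, outdated ordering, RAM dump
type) defeat the integrity mitigations themselves and always abort;
comparing RAM exports requires its own dedicated flag (`--allow-ram`), which
stamps a deviation banner on the head of every report format.  Timestamp
comparison is strict: equal export instants are treated as outdated.  Range
checks were made fatal-but-ignorable — fatal because an out-of-range
treatment parameter must block a checklist, ignorable because research-mode
comparisons of experimental settings are the stated use of the override.

## Comparison

Alignment is three-level (DCU → setting → parameter) and totally ordered by
(DCU id, setting key, parameter name).  Numeric values compare numerically —
formatting-only edits are not differences — and non-numeric values by exact
text.  The default tolerance is **zero**: nothing in the safety argument
licenses silent suppression of small changes, so tolerances exist only as
explicit configuration (absolute or relative per parameter, YAML).  A DCU
missing on one side is a single structural difference; at the QA stage a
structural difference triggers all of the device's influences.

## QA mapping

The knowledge base is a plain tab-separated text file (id, device name,
influence list, room list, with version/facility directives) — deliberately
reviewable and diffable under version control, since incorrect device
entries are the principal knowledge-base hazard.  All invariants are
enforced at load time with distinct error codes.

QA procedures map 1:1 to beam influences (energy, focus, intensity,
position check); additional procedures would attach via the KB format.  The
checklist is the union of influence × room products over changed devices,
aggregated into one item per (room, procedure) pair carrying every
triggering difference.  QA extent is binary per procedure and room; grading
by difference magnitude was considered and rejected as unverifiable without
facility-specific dose models.  An unresolved changed device escalates to
every procedure in every room rather than erroring, because that state is
only reachable when matching findings were deliberately ignored —
fail-safety is preserved even in degraded mode.

## Synthetic data

The generator emulates the facility at an adjustable `scale`: the DCU
inventory is `ceil(scale · 177)` and every grid axis `ceil(scale · steps)`
(minimum 1), so scale 1 reproduces the facility constants exactly and the
desk scale 0.05 (9 DCUs, 13 energy steps, 2 angle nodes) keeps test corpora
fast.  Devices are drawn from an invented, replaceable taxonomy (dipole,
quadrupole, RF cavity, scanner magnet, beam monitor, steerer, collimator)
whose class fixes the beam influences; affected rooms are drawn per device
from weighted room subsets, with at least one gantry-only device guaranteed.
Each setting carries the physical MEFI echo parameters, class-specific
device parameters drawn uniformly from plausible engineering ranges, and
padding up to 10 parameters per setting (a stated placeholder — real
per-device parameter counts are facility-internal).  All randomness is
seeded and the full chain (seed, scale, plan) → bytes is deterministic.

Injected edits keep beam parameters inside their physical range (drawing a
distinct in-range value) unless a request explicitly asks for an
out-of-range value, so uncorrupted pairs validate cleanly — the
generator/validator closure that makes the injection ledger a usable ground
truth.  Eight corruption modes (bad checksum, schema violation, malformed
XML, RAM dump type, stale timestamp, identical pair, unknown DCU,
out-of-range value) each trigger exactly one mapped finding or read error.

What the generator does **not** emulate: real device parameter values and
their correlations, production export sizes (~500 MB), per-room step
tables, partial/incremental flash procedures, or vendor-specific XML
quirks.  Green tests therefore demonstrate the engine's alignment,
integrity and fail-safe logic, not numerical agreement with any real
facility's libraries.

## Problem sizes and numerical choices

The behavioural suites run on 200 seeded pairs at scale 0.05 with 1–8
injected edits each (the acceptance script uses the same corpus size);
property tests use scale 0.02.  Numeric equality in comparison is exact by
default; the gantry multiple check uses a 1e-9 relative tolerance;
floating-point step values are rounded to 6 decimals in generated dumps so
canonical texts stay short.  Ties cannot arise in ordering (keys are
unique), and degenerate inputs (empty dumps, empty plans, single-step axes)
are exercised in the tests.

## Known limitations

- In-memory parsing only; no streaming for production-size exports.
- One payload checksum per dump (no per-device digests).
- The QA checklist does not estimate QA duration or grade extent.
- The dialect, flag names and exit codes are this package's own; importing
  a real facility's export format would require a format adapter.
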