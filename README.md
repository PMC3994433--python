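# flashdiff

Configuration-diff and QA-selection tooling for ion-beam therapy facilities.

At a synchrotron-based dual-species facility (protons and carbon ions, two
fixed horizontal treatment rooms plus one 360° gantry), every beamline device
is driven by a device control unit (DCU) that stores one parameter set per
validated beam setting.  Settings are addressed by **MEFI** tuples — Machine
(ion species), Energy step, Focus step, Intensity step — and the
treatment-validated MEFI libraries live in the flash memory of all 177 DCUs.
After accelerator maintenance or beam adjustments those libraries change, and
the full beam QA program (all parameters, all rooms) takes on the order of
days.  The pragmatic alternative is *differential* QA: export the MEFI
libraries before and after the intervention ("flashdumps", XML), diff them,
and re-qualify only the beam properties actually touched, only in the rooms
actually affected.

`flashdiff` is that decision-support pipeline, written for medical physicists
and accelerator engineers:

1. **Integrity validation** of the flashdump pair before anything else:
   XSD-schema conformance, header consistency (DCU count, SHA-256 payload
   checksum), dump type (flash-memory exports only, unless a dedicated RAM
   flag is set), strict timestamp ordering, non-identity, physical range of
   every beam parameter, and bidirectional DCU matching against the
   knowledge base.  Any fatal finding blocks the QA checklist.
2. **Three-level diff** (DCU → MEFI/angle node → parameter) with numeric
   comparison under an explicit, default-zero tolerance policy.
3. **Rule mapping**: each changed device is looked up in a curated knowledge
   base giving its *beam influences* (energy, focus, intensity, position)
   and affected rooms; the checklist is the union of influence × room
   products over all changed devices.  A changed device that cannot be
   resolved escalates to full QA everywhere.

The governing safety contract is **fail-safety against false negatives**: a
result print saying "no QA required" while a treatment-relevant parameter
changed is the worst case, and the package makes it structurally impossible —
a non-empty difference set never yields that verdict, output filters only
ever restrict the display (never the checklist), the research-mode `--ignore`
flag can downgrade a run to a diff-only print but never re-enable a
checklist, and integrity-defeating findings (checksum, dump type, ordering)
cannot be ignored at all.

No real facility export is publicly available, so the package ships a
first-class synthetic generator that emulates a realistic facility (177
DCUs, the standard treatment grids, 2 + 1 room topology) and produces
seeded flashdump pairs with an exact injection ledger plus eight corruption
modes — the test bed for every guarantee above.

## Worked example

Generate a self-contained desk-scale test kit (9 DCUs, 2 injected edits) and
compare the pair:

```
$ flashdiff generate --seed 7 --scale 0.05 --edits 2 --out kit --corruptions
test kit written to kit (9 DCUs, 2 edits)

$ flashdiff compare --last kit/last.xml --current kit/current.xml \
      --kb kit/knowledge_base.kb --grids kit/grids.yaml --out run
$ cat run/report.txt
FLASHDUMP COMPARISON RESULT
============================================================
tool version:       1.0.0
knowledge base:     version kb-7.9
last dump:
  type flash  exported 2025-06-01T08:00:00Z  facility SYN-00000007
  checksum f3a828b4ceff71f8ac4d0f2e0577a184fdda310b2c86673870693f202908f7be
current dump:
  type flash  exported 2025-06-01T09:00:00Z  facility SYN-00000007
  checksum 6ed0ad68c77fd47eecc603a551d27713445dd65fc4635b413d0d51bef37a9f5e

VALIDATION: passed

DIFFERENCES (2 shown)
  DCU-004/carbon/e0/f0/i0/aux_01: 0.032237 -> -0.002245
  DCU-005/proton/e12/f0/i0/aux_05: 0.810037 -> 1.642348

QA CHECKLIST — verdict: qa_required
  room G1:
    - beam intensity check (triggered by DCU-005)
    - beam position check (triggered by DCU-004, DCU-005)
  room H1:
    - beam intensity check (triggered by DCU-005)
    - beam position check (triggered by DCU-004, DCU-005)
  room H2:
    - beam intensity check (triggered by DCU-005)
    - beam position check (triggered by DCU-004, DCU-005)
```

Reading: two device parameters changed between the exports.  `DCU-004` is a
scanner magnet influencing beam position, `DCU-005` a beam monitor
influencing intensity and position; per the knowledge base their changes
affect all three rooms, so
before treatment resumes the intensity and position of the beam must be
re-checked in H1, H2 and G1 — and nothing else (no energy or focus QA, no
untouched rooms).  The exit code only reports that the run completed; the
verdict lives in the report so that scripting mistakes can never turn a
failure into "no QA required".  `run/` additionally holds machine-readable
`differences.json` and `findings.json`.

Validation failures abort before any checklist is derived, e.g. comparing a
RAM export without the dedicated flag:

```
$ flashdiff compare --last kit/last.xml \
      --current kit/corrupted/ram_dump_type_current.xml ... --out run2
# exit status 66; run2/findings.json names ram_dump_forbidden
```

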