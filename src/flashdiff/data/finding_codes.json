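{
  "format": "flashdiff finding catalogue",
  "version": "1.0",
  "codes": {
    "malformed_xml": {
      "layer": "read",
      "severity": "fatal",
      "ignorable": false,
      "description": "Input is not well-formed XML; raised while reading, before validation."
    },
    "schema_violation": {
      "layer": "read",
      "severity": "fatal",
      "ignorable": false,
      "description": "Input violates the flashdump XSD dialect; raised while reading, before validation."
    },
    "not_processable": {
      "layer": "read",
      "severity": "fatal",
      "ignorable": false,
      "description": "Input file or stream missing or unreadable."
    },
    "header_count_mismatch": {
      "layer": "validation",
      "stage": 1,
      "severity": "fatal",
      "ignorable": true,
      "description": "Declared dcu_count differs from the number of DCU records in the body."
    },
    "checksum_mismatch": {
      "layer": "validation",
      "stage": 1,
      "severity": "fatal",
      "ignorable": false,
      "description": "Declared payload checksum differs from the checksum recomputed over the body; the dump cannot be trusted."
    },
    "facility_mismatch": {
      "layer": "validation",
      "stage": 1,
      "severity": "fatal",
      "ignorable": true,
      "description": "Facility identifiers of the two dumps, or of dumps and knowledge base, disagree."
    },
    "ram_dump_forbidden": {
      "layer": "validation",
      "stage": 2,
      "severity": "fatal",
      "ignorable": false,
      "description": "A RAM export was supplied without the dedicated RAM-comparison flag; only flash-memory exports are compared by default."
    },
    "outdated_dumps": {
      "layer": "validation",
      "stage": 3,
      "severity": "fatal",
      "ignorable": false,
      "description": "The current dump's export timestamp is not strictly later than the last dump's."
    },
    "identical_dumps": {
      "layer": "validation",
      "stage": 3,
      "severity": "fatal",
      "ignorable": false,
      "description": "Both dumps carry the same payload checksum; comparing identical exports is meaningless and indicates an operating error."
    },
    "out_of_range": {
      "layer": "validation",
      "stage": 4,
      "severity": "fatal",
      "ignorable": true,
      "description": "A beam-parameter value lies outside the treatment-validated range for its species."
    },
    "invalid_mefi_index": {
      "layer": "validation",
      "stage": 4,
      "severity": "fatal",
      "ignorable": true,
      "description": "A MEFI or angle-node index lies outside the configured grid for its species."
    },
    "unknown_species": {
      "layer": "validation",
      "stage": 4,
      "severity": "fatal",
      "ignorable": true,
      "description": "A setting references an ion species absent from the grid registry."
    },
    "unknown_dcu": {
      "layer": "validation",
      "stage": 5,
      "severity": "fatal",
      "ignorable": true,
      "description": "A DCU present in a dump has no knowledge-base entry; its beam influence cannot be resolved."
    },
    "missing_dcu": {
      "layer": "validation",
      "stage": 5,
      "severity": "fatal",
      "ignorable": true,
      "description": "A DCU listed in the knowledge base is absent from a dump."
    }
  }
}
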