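{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ustrina analysis report",
  "type": "object",
  "required": [
    "schema_version",
    "provenance",
    "totals",
    "composition_shares_pct",
    "indices",
    "spatial",
    "mni"
  ],
  "properties": {
    "schema_version": {"type": "string"},
    "provenance": {
      "type": "object",
      "required": ["tool", "version", "config"],
      "properties": {
        "tool": {"type": "string"},
        "version": {"type": "string"},
        "input_sha256": {"type": ["string", "null"]},
        "seed": {"type": ["integer", "null"]},
        "config": {"type": "object"}
      }
    },
    "totals": {
      "type": "object",
      "required": ["total_g", "by_us", "n_records"],
      "properties": {
        "total_g": {"type": "number", "minimum": 0},
        "by_us": {"type": "object"},
        "n_records": {"type": "integer", "minimum": 0}
      }
    },
    "composition_shares_pct": {
      "type": "object",
      "additionalProperties": {"type": "number", "minimum": 0, "maximum": 100}
    },
    "indices": {
      "type": "object",
      "required": ["fragmentation_index", "cpc_index"],
      "additionalProperties": true
    },
    "spatial": {"type": "object"},
    "mni": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["scenario", "mode", "unit_count", "counts", "mni", "modelled_g", "misfit_g"],
        "properties": {
          "scenario": {"type": "string"},
          "mode": {"enum": ["primary", "residual"]},
          "unit_count": {"type": "integer", "minimum": 0},
          "counts": {"type": "object"},
          "mni": {"type": "integer", "minimum": 0},
          "modelled_g": {"type": "number", "minimum": 0},
          "misfit_g": {"type": "number"}
        }
      }
    }
  }
}
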