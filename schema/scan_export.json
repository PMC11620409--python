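{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "pxrfkit/scan_export.json",
  "title": "pXRF scan export",
  "description": "One instrument scan: metadata, three raw beam spectra of 2048 channels, and a 42-element concentration table. This dialect is defined by pxrfkit; runtime validation is performed by the pydantic models in pxrfkit.io_vanta, which this document mirrors.",
  "type": "object",
  "required": ["metadata", "spectra", "concentrations"],
  "additionalProperties": false,
  "properties": {
    "metadata": {
      "type": "object",
      "required": ["export_id", "specimen_id", "taxon", "location", "state", "dwell_time_s", "backed", "replicate"],
      "additionalProperties": false,
      "properties": {
        "export_id": {"type": "string"},
        "specimen_id": {"type": "string"},
        "taxon": {"type": "string"},
        "location": {"type": "string", "description": "body location scanned"},
        "state": {"enum": ["thawed", "dried", "natural"]},
        "dwell_time_s": {"type": "number", "exclusiveMinimum": 0},
        "backed": {"type": "boolean", "description": "silica block behind the sample"},
        "replicate": {"type": "integer", "minimum": 1},
        "instrument_method": {"type": "string"},
        "timestamp": {"type": "string", "description": "ISO-8601"}
      }
    },
    "spectra": {
      "type": "array",
      "minItems": 3,
      "maxItems": 3,
      "items": {
        "type": "object",
        "required": ["beam_index", "beam_energy_kev", "live_time_s", "gain_kev_per_channel", "counts"],
        "additionalProperties": false,
        "properties": {
          "beam_index": {"type": "integer", "minimum": 1, "maximum": 3},
          "beam_energy_kev": {"type": "number", "exclusiveMinimum": 0},
          "live_time_s": {"type": "number", "exclusiveMinimum": 0},
          "gain_kev_per_channel": {"type": "number", "exclusiveMinimum": 0},
          "offset_kev": {"type": "number"},
          "counts": {
            "type": "array",
            "minItems": 2048,
            "maxItems": 2048,
            "items": {"type": "integer", "minimum": 0}
          }
        }
      }
    },
    "concentrations": {
      "type": "array",
      "minItems": 42,
      "maxItems": 42,
      "items": {
        "type": "object",
        "required": ["element", "below_lod"],
        "additionalProperties": false,
        "properties": {
          "element": {"type": "string"},
          "below_lod": {"type": "boolean"},
          "concentration_pct": {"type": ["number", "null"], "minimum": 0},
          "error_1sigma_pct": {"type": ["number", "null"], "minimum": 0}
        }
      }
    }
  }
}
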