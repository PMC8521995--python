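{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Squat set score report",
  "type": "object",
  "required": ["rounds", "sum_index1", "sum_index2", "sum_index3", "grand_total", "volume_envelope"],
  "properties": {
    "source_id": {"type": "string"},
    "t0": {"type": "number", "minimum": 0},
    "set_config": {
      "type": "object",
      "properties": {
        "n_rounds": {"type": "integer", "minimum": 1},
        "round_duration": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "rounds": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["round", "index1", "index2", "index3", "total"],
        "properties": {
          "round": {"type": "integer", "minimum": 1},
          "index1": {"type": "integer", "minimum": 0, "maximum": 3},
          "index2": {"type": "integer", "minimum": 0, "maximum": 3},
          "index3": {"type": "integer", "minimum": 0, "maximum": 4},
          "total": {"type": "integer", "minimum": 0, "maximum": 10},
          "diagnostics": {"type": "object"}
        }
      }
    },
    "sum_index1": {"type": "integer", "minimum": 0, "maximum": 30},
    "sum_index2": {"type": "integer", "minimum": 0, "maximum": 30},
    "sum_index3": {"type": "integer", "minimum": 0, "maximum": 40},
    "grand_total": {"type": "integer", "minimum": 0, "maximum": 100},
    "volume_envelope": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["round", "bgm_pct", "noise_pct"],
        "properties": {
          "round": {"type": "integer", "minimum": 1},
          "bgm_pct": {"type": "number", "minimum": 0, "maximum": 100},
          "noise_pct": {"type": "number", "minimum": 0, "maximum": 100}
        }
      }
    }
  }
}
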