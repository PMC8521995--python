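{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Cohort descriptive summary",
  "type": "object",
  "propertyNames": {"enum": ["younger", "middle", "older", "all"]},
  "additionalProperties": {
    "type": "object",
    "required": ["n"],
    "properties": {
      "n": {"type": "integer", "minimum": 0},
      "age": {
        "type": "object",
        "properties": {
          "mean": {"type": "number"},
          "sd": {"type": "number"},
          "min": {"type": "number"},
          "max": {"type": "number"}
        }
      },
      "gender": {"$ref": "#/$defs/categoryBlock"},
      "exercise_change": {"$ref": "#/$defs/categoryBlock"},
      "habit": {"$ref": "#/$defs/categoryBlock"}
    }
  },
  "$defs": {
    "categoryBlock": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["n", "pct"],
        "properties": {
          "n": {"type": "integer", "minimum": 0},
          "pct": {"type": "number", "minimum": 0, "maximum": 100}
        }
      }
    }
  }
}
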