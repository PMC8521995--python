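{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Pose keypoint trajectory",
  "type": "object",
  "required": ["fps", "frames"],
  "properties": {
    "fps": {"type": "number", "exclusiveMinimum": 0},
    "source_id": {"type": "string"},
    "frames": {
      "type": "array",
      "minItems": 2,
      "items": {
        "type": "object",
        "required": ["t", "keypoints"],
        "properties": {
          "t": {"type": "number", "minimum": 0},
          "keypoints": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["part", "x", "y", "score"],
              "properties": {
                "part": {
                  "enum": [
                    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
                    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
                    "left_wrist", "right_wrist", "left_hip", "right_hip",
                    "left_knee", "right_knee", "left_ankle", "right_ankle"
                  ]
                },
                "x": {"type": "number"},
                "y": {"type": "number"},
                "score": {"type": "number", "minimum": 0, "maximum": 1}
              }
            }
          }
        }
      }
    }
  }
}
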