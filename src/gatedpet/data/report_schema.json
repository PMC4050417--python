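{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "gatedpet comparison report",
  "type": "object",
  "required": ["rows", "summary", "wilcoxon", "n_lesions"],
  "properties": {
    "rows": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["patient", "lesion", "ptv_cc", "ptvg_cc", "bitv_cc", "btv_cc"],
        "properties": {
          "patient": {"type": "integer"},
          "lesion": {"type": "integer"},
          "ptv_cc": {"type": "number", "minimum": 0},
          "ptvg_cc": {"type": "number", "minimum": 0},
          "ptv_over_ptvg_pct": {"type": ["integer", "null"]},
          "bitv_cc": {"type": "number", "minimum": 0},
          "btv_cc": {"type": "number", "minimum": 0},
          "bitv_over_btv_pct": {"type": ["integer", "null"]},
          "ctv_cc": {"type": ["number", "null"]},
          "liver_cc": {"type": ["number", "null"]}
        }
      }
    },
    "summary": {
      "type": "object",
      "required": [
        "mean_ptv_cc", "mean_ptvg_cc", "mean_bitv_cc", "mean_btv_cc",
        "ratio_of_means_ptv_over_ptvg_pct", "ratio_of_means_bitv_over_btv_pct"
      ]
    },
    "wilcoxon": {
      "type": "object",
      "required": ["ptv_vs_ptvg", "bitv_vs_btv"],
      "properties": {
        "ptv_vs_ptvg": {"$ref": "#/definitions/test"},
        "bitv_vs_btv": {"$ref": "#/definitions/test"}
      }
    },
    "n_lesions": {"type": "integer", "minimum": 1}
  },
  "definitions": {
    "test": {
      "type": "object",
      "required": ["p", "W", "n", "method"],
      "properties": {
        "p": {"type": "number", "minimum": 0, "maximum": 1},
        "W": {"type": "number", "minimum": 0},
        "n": {"type": "integer", "minimum": 0},
        "method": {"enum": ["exact", "approximate"]},
        "degenerate": {"type": "boolean"}
      }
    }
  }
}
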