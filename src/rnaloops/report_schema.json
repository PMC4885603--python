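{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "rnaloops-report-1.0",
  "title": "rnaloops annotation report",
  "type": "object",
  "required": ["schema_version", "length", "dotbracket", "stems", "ecrs", "loops", "signatures"],
  "properties": {
    "schema_version": {"const": "1.0"},
    "name": {"type": ["string", "null"]},
    "length": {"type": "integer", "minimum": 0},
    "sequence": {"type": ["string", "null"]},
    "dotbracket": {"type": "string"},
    "stems": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "face", "internal_pair", "left_wing", "right_wing", "n_pairs", "type"],
        "properties": {
          "id": {"type": "integer"},
          "face": {"$ref": "#/$defs/interval"},
          "internal_pair": {"$ref": "#/$defs/interval"},
          "left_wing": {"$ref": "#/$defs/interval"},
          "right_wing": {"$ref": "#/$defs/interval"},
          "n_pairs": {"type": "integer", "minimum": 1},
          "type": {"enum": ["standard", "arbitrary"]}
        }
      }
    },
    "isolated_pairs": {"type": "array", "items": {"$ref": "#/$defs/interval"}},
    "ecrs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "interval", "kind", "parent", "depth", "member_stems"],
        "properties": {
          "id": {"type": "integer"},
          "interval": {"$ref": "#/$defs/interval"},
          "kind": {"enum": ["classical", "pseudoknotted"]},
          "parent": {"type": ["integer", "null"]},
          "depth": {"type": "integer", "minimum": 0},
          "member_stems": {"type": "array", "items": {"type": "integer"}}
        }
      }
    },
    "exterior_segments": {"type": "array", "items": {"$ref": "#/$defs/interval"}},
    "loops": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["stem", "sides", "faces", "wings_contained", "size_class", "pk_class"],
        "properties": {
          "stem": {"type": "integer"},
          "sides": {"type": "array", "items": {"$ref": "#/$defs/interval"}},
          "faces": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["i", "j", "tag"],
              "properties": {
                "i": {"type": "integer"},
                "j": {"type": "integer"},
                "tag": {"enum": ["stem_face", "pseudoknot_face"]}
              }
            }
          },
          "wings_contained": {"type": "array", "items": {"$ref": "#/$defs/interval"}},
          "size_class": {"enum": ["hairpin", "internal", "bulge", "multiple_junction"]},
          "pk_class": {"enum": ["classical", "isolated", "pseudoknotted"]}
        }
      }
    },
    "signatures": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["ecr", "full", "upper", "reduced", "named_class"],
        "properties": {
          "ecr": {"type": "integer"},
          "full": {"type": "string"},
          "upper": {"type": "string"},
          "reduced": {"type": "string"},
          "named_class": {"enum": ["H_knot", "kissing_hairpins", "triple_knot", "other"]}
        }
      }
    }
  },
  "$defs": {
    "interval": {
      "type": "array",
      "items": {"type": "integer"},
      "minItems": 2,
      "maxItems": 2
    }
  }
}
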