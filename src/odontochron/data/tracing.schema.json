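{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "odontochron-tracing/1",
  "title": "Digitized tooth thin-section tracing",
  "description": "Planar (µm) tracing of one longitudinal section: EDJ polyline (dentine horn to cervix), closed enamel outline, 200-µm prism segment traces, striae (retzius/accentuated/neonatal) and cross-striation run measurements.",
  "type": "object",
  "required": ["schema", "id", "arch", "wear_stage", "edj", "enamel_outline"],
  "properties": {
    "schema": {"const": "odontochron-tracing/1"},
    "id": {"type": "string"},
    "site": {"type": "string"},
    "arch": {"enum": ["upper", "lower"]},
    "side": {"type": "string"},
    "sex": {"enum": ["M", "F", "unknown"]},
    "wear_stage": {"type": "integer", "minimum": 1, "maximum": 8},
    "flags": {
      "type": "object",
      "properties": {
        "worn_horn": {"type": "boolean"},
        "broken_cervix": {"type": "boolean"},
        "exclude_cc": {"type": "boolean"}
      }
    },
    "edj": {"$ref": "#/$defs/polyline"},
    "enamel_outline": {"$ref": "#/$defs/polyline"},
    "prisms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["index", "path", "start_on_edj"],
        "properties": {
          "index": {"type": "integer", "minimum": 1},
          "path": {"$ref": "#/$defs/polyline"},
          "start_on_edj": {"$ref": "#/$defs/point"},
          "terminal_stria": {"type": ["string", "null"]}
        }
      }
    },
    "striae": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "path"],
        "properties": {
          "id": {"type": "string"},
          "kind": {"enum": ["retzius", "accentuated", "neonatal"]},
          "path": {"$ref": "#/$defs/polyline"}
        }
      }
    },
    "runs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["segment_index", "run_length", "n_striations"],
        "properties": {
          "segment_index": {"type": "integer", "minimum": 1},
          "run_length": {"type": "number", "exclusiveMinimum": 0},
          "n_striations": {"type": "integer", "minimum": 1}
        }
      }
    }
  },
  "$defs": {
    "point": {
      "type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2
    },
    "polyline": {
      "type": "array", "items": {"$ref": "#/$defs/point"}, "minItems": 2
    }
  }
}
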