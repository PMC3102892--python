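{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Hypothesis document",
  "description": "A hypothesis is a tree whose leaves are hypothesized molecular events and whose internal nodes are n-ary AND/OR/XOR operators (>=2 children). This file documents the dialect; the parser performs equivalent validation natively.",
  "type": "object",
  "required": ["root"],
  "properties": {
    "id": {"type": "string"},
    "title": {"type": "string"},
    "root": {"$ref": "#/$defs/node"}
  },
  "$defs": {
    "node": {
      "oneOf": [
        {
          "type": "object",
          "required": ["event"],
          "properties": {"event": {"$ref": "#/$defs/event"}},
          "additionalProperties": false
        },
        {
          "type": "object",
          "required": ["operator", "children"],
          "properties": {
            "operator": {"enum": ["AND", "OR", "XOR"]},
            "children": {
              "type": "array",
              "minItems": 2,
              "items": {"$ref": "#/$defs/node"}
            }
          },
          "additionalProperties": false
        }
      ]
    },
    "event": {
      "type": "object",
      "required": ["event_type", "relation", "actor", "target"],
      "properties": {
        "label": {"type": "string"},
        "event_type": {
          "enum": [
            "protein-protein-binding",
            "protein-nucleic-acid-binding",
            "activation",
            "inhibition",
            "induction",
            "repression",
            "transport"
          ]
        },
        "relation": {"type": "string"},
        "actor": {"$ref": "#/$defs/entity_ref"},
        "target": {"$ref": "#/$defs/entity_ref"},
        "location": {"type": "string", "description": "GO CURIE"},
        "context": {"type": "string", "default": "wt"},
        "negated_claim": {"type": "boolean", "default": false}
      }
    },
    "entity_ref": {
      "type": "object",
      "description": "Exactly one of: {instance}, {type}, {variable[, type]}.",
      "properties": {
        "instance": {"type": "string", "description": "entity CURIE"},
        "type": {"type": "string", "description": "ontology CURIE restriction"},
        "variable": {"type": "string", "description": "?-prefixed query variable"}
      },
      "minProperties": 1
    }
  }
}
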