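{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "smda native network document",
  "description": "Canonical JSON serialization of a MetabolicNetwork. Entity lists are sorted by id; all cross-references are ids declared earlier in the document.",
  "type": "object",
  "required": ["format", "version", "name", "compartments", "metabolites", "pools", "reactions", "pathways"],
  "properties": {
    "format": {"const": "smda-network"},
    "version": {"const": 1},
    "name": {"type": "string"},
    "compartments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "parent"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "parent": {"type": ["string", "null"]}
        }
      }
    },
    "metabolites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "synonyms"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "synonyms": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "pools": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "metabolite", "compartment"],
        "properties": {
          "id": {"type": "string"},
          "metabolite": {"type": "string"},
          "compartment": {"type": "string"}
        }
      }
    },
    "reactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "reversible", "enzymes", "participants"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "reversible": {"type": "boolean"},
          "enzymes": {"type": "array", "items": {"type": "string"}},
          "collapsed_from": {"type": ["string", "null"]},
          "participants": {
            "type": "array",
            "minItems": 2,
            "items": {
              "type": "object",
              "required": ["pool", "role"],
              "properties": {
                "pool": {"type": "string"},
                "role": {"enum": ["substrate", "product", "activator", "inhibitor"]}
              }
            }
          }
        }
      }
    },
    "pathways": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "reactions", "compartments"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "reactions": {"type": "array", "minItems": 1, "items": {"type": "string"}},
          "compartments": {"type": "array", "minItems": 1, "items": {"type": "string"}}
        }
      }
    }
  }
}
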