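{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "smda CLI run configuration",
  "description": "YAML or JSON mapping accepted by `smda --config`. All keys optional.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "strategy": {"enum": ["breadth_first", "depth_first"]},
    "cap": {"type": "integer", "minimum": 1, "description": "Scenario cap (default 10000)."},
    "seed": {"type": "integer", "description": "Depth-first tie-break seed."},
    "currency": {
      "type": "array",
      "items": {"type": "string"},
      "description": "Currency metabolite names for queries and GraphML export."
    },
    "modifier_roles": {
      "type": "object",
      "additionalProperties": {"enum": ["enzyme", "inhibitor", "activator"]},
      "description": "SBML modifier species id -> role override."
    },
    "log_level": {"enum": ["DEBUG", "INFO", "WARNING", "ERROR"]}
  }
}
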