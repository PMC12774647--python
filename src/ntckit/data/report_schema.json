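{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ntckit report",
  "description": "Schema shared by the annotation and validation JSON reports.",
  "type": "object",
  "required": ["entry_id", "kind", "summary"],
  "properties": {
    "entry_id": {"type": "string"},
    "kind": {"type": "string", "enum": ["annotation", "validation"]},
    "summary": {"type": "object"},
    "steps": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["step_id", "ntc", "cana", "confal", "rmsd"],
        "properties": {
          "step_id": {"type": "string"},
          "ntc": {"type": "string"},
          "cana": {"type": "string"},
          "confal": {"type": "number", "minimum": 0, "maximum": 100},
          "rmsd": {"type": "number", "minimum": 0}
        }
      }
    },
    "terms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["term_name", "term_type", "observed", "prosco", "zprime", "tier", "support"],
        "properties": {
          "term_name": {"type": "string"},
          "term_type": {"type": "string", "enum": ["bond", "angle"]},
          "observed": {"type": "number"},
          "prosco": {"type": "number", "minimum": 0, "maximum": 100},
          "zprime": {"type": "number"},
          "tier": {"type": "string", "enum": ["Preferred", "Allowed", "OfConcern"]},
          "support": {"type": "string", "enum": ["Common", "Rare", "Ambiguous", "Unique"]}
        }
      }
    }
  }
}
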