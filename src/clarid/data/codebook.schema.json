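{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/clarid/codebook.schema.json",
  "title": "ClarID codebook",
  "type": "object",
  "required": ["biosample", "subject"],
  "properties": {
    "biosample": {
      "type": "object",
      "required": ["project", "species", "tissue", "sample_type", "assay", "timepoint"],
      "properties": {
        "project": { "$ref": "#/$defs/free_component" },
        "species": { "$ref": "#/$defs/component" },
        "tissue": { "$ref": "#/$defs/component" },
        "sample_type": { "$ref": "#/$defs/component" },
        "assay": { "$ref": "#/$defs/component" },
        "timepoint": { "$ref": "#/$defs/component" }
      }
    },
    "subject": {
      "type": "object",
      "required": ["type", "sex", "age_group"],
      "properties": {
        "study": { "$ref": "#/$defs/free_component" },
        "type": { "$ref": "#/$defs/component" },
        "sex": { "$ref": "#/$defs/component" },
        "age_group": { "$ref": "#/$defs/component" }
      }
    },
    "rules": {
      "type": "object",
      "patternProperties": {
        "^[a-z_]+$": { "type": "string", "minLength": 1 }
      }
    }
  },
  "$defs": {
    "component": {
      "type": "object",
      "minProperties": 1,
      "patternProperties": {
        "": { "$ref": "#/$defs/entry" }
      }
    },
    "free_component": {
      "type": "object",
      "minProperties": 1,
      "patternProperties": {
        "": { "$ref": "#/$defs/free_entry" }
      }
    },
    "entry": {
      "type": "object",
      "required": ["code", "stub_code"],
      "properties": {
        "code": { "type": "string", "minLength": 1, "pattern": "^[A-Za-z0-9_.]+$" },
        "stub_code": { "type": "string", "minLength": 1, "pattern": "^[A-Za-z0-9]+$" },
        "label": { "type": "string" },
        "id": { "type": "string", "pattern": "^[A-Za-z0-9_.]+:[A-Za-z0-9_.]+$" },
        "tax_code": { "type": "string", "pattern": "^[A-Z]{3}$" }
      }
    },
    "free_entry": {
      "type": "object",
      "required": ["code"],
      "properties": {
        "code": { "type": "string", "minLength": 1, "pattern": "^[A-Za-z0-9_.]+$" },
        "stub_code": { "type": "string", "minLength": 1, "pattern": "^[A-Za-z0-9]+$" },
        "label": { "type": "string" },
        "id": { "type": "string", "pattern": "^[A-Za-z0-9_.]+:[A-Za-z0-9_.]+$" }
      }
    }
  }
}
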