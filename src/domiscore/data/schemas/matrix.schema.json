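{
 "$defs": {
  "VulnerabilityRule": {
   "additionalProperties": false,
   "description": "One penalty rule: +1 point on ``variable_id`` when the named\nvulnerability is present and the pre-penalty score reaches\n``trigger_threshold``.",
   "properties": {
    "vulnerability": {
     "enum": [
      "young_children_u4",
      "elderly_o70",
      "physical_disability",
      "visual_disability",
      "hearing_disability"
     ],
     "title": "Vulnerability",
     "type": "string"
    },
    "variable_id": {
     "title": "Variable Id",
     "type": "string"
    },
    "trigger_threshold": {
     "title": "Trigger Threshold",
     "type": "integer"
    },
    "penalty_points": {
     "const": 1,
     "default": 1,
     "title": "Penalty Points",
     "type": "integer"
    },
    "note": {
     "default": "",
     "title": "Note",
     "type": "string"
    }
   },
   "required": [
    "vulnerability",
    "variable_id",
    "trigger_threshold"
   ],
   "title": "VulnerabilityRule",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "The full rule table for a given grid version.",
 "properties": {
  "schema_version": {
   "default": "1",
   "title": "Schema Version",
   "type": "string"
  },
  "grid_version": {
   "title": "Grid Version",
   "type": "string"
  },
  "note": {
   "default": "",
   "title": "Note",
   "type": "string"
  },
  "rules": {
   "items": {
    "$ref": "#/$defs/VulnerabilityRule"
   },
   "title": "Rules",
   "type": "array"
  }
 },
 "required": [
  "grid_version"
 ],
 "title": "VulnerabilityMatrix",
 "type": "object"
}
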