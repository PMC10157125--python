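{
 "$defs": {
  "CategoryDefinition": {
   "additionalProperties": false,
   "description": "A thematic category: an ordered, non-empty group of variables.",
   "properties": {
    "id": {
     "title": "Id",
     "type": "string"
    },
    "label": {
     "title": "Label",
     "type": "string"
    },
    "variable_ids": {
     "items": {
      "type": "string"
     },
     "minItems": 1,
     "title": "Variable Ids",
     "type": "array"
    }
   },
   "required": [
    "id",
    "label",
    "variable_ids"
   ],
   "title": "CategoryDefinition",
   "type": "object"
  },
  "VariableDefinition": {
   "additionalProperties": false,
   "description": "One scorable housing characteristic.\n\n``level_descriptions`` must describe exactly the four ordinal levels\n0-3; ``alert_threshold``, when set, is the level (1, 2 or 3) at which\nreporting to authorities is required.",
   "properties": {
    "id": {
     "title": "Id",
     "type": "string"
    },
    "label": {
     "title": "Label",
     "type": "string"
    },
    "category_id": {
     "title": "Category Id",
     "type": "string"
    },
    "position": {
     "minimum": 1,
     "title": "Position",
     "type": "integer"
    },
    "sources": {
     "items": {
      "enum": [
       "in_situ",
       "mandatory_diagnostic",
       "open_data",
       "occupant_report"
      ],
      "type": "string"
     },
     "minItems": 1,
     "title": "Sources",
     "type": "array"
    },
    "level_descriptions": {
     "additionalProperties": {
      "type": "string"
     },
     "title": "Level Descriptions",
     "type": "object"
    },
    "alert_threshold": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Alert Threshold"
    },
    "notes": {
     "default": "",
     "title": "Notes",
     "type": "string"
    }
   },
   "required": [
    "id",
    "label",
    "category_id",
    "position",
    "sources",
    "level_descriptions"
   ],
   "title": "VariableDefinition",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "A versioned Domiscore grid: ordered categories plus their variables.",
 "properties": {
  "schema_version": {
   "default": "1",
   "title": "Schema Version",
   "type": "string"
  },
  "version": {
   "title": "Version",
   "type": "string"
  },
  "note": {
   "default": "",
   "title": "Note",
   "type": "string"
  },
  "categories": {
   "items": {
    "$ref": "#/$defs/CategoryDefinition"
   },
   "title": "Categories",
   "type": "array"
  },
  "variables": {
   "items": {
    "$ref": "#/$defs/VariableDefinition"
   },
   "title": "Variables",
   "type": "array"
  }
 },
 "required": [
  "version",
  "categories",
  "variables"
 ],
 "title": "GridDefinition",
 "type": "object"
}
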