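{
 "$defs": {
  "DwellingMeta": {
   "additionalProperties": false,
   "description": "Anonymous dwelling metadata recorded at the visit.",
   "properties": {
    "housing_type": {
     "default": "collective",
     "enum": [
      "collective",
      "individual"
     ],
     "title": "Housing Type",
     "type": "string"
    },
    "setting": {
     "default": "urban",
     "enum": [
      "urban",
      "rural"
     ],
     "title": "Setting",
     "type": "string"
    },
    "overseas": {
     "default": false,
     "title": "Overseas",
     "type": "boolean"
    },
    "tenure": {
     "default": "private_rental",
     "enum": [
      "owner_occupant",
      "private_rental",
      "social_housing"
     ],
     "title": "Tenure",
     "type": "string"
    },
    "typology": {
     "default": "",
     "title": "Typology",
     "type": "string"
    }
   },
   "title": "DwellingMeta",
   "type": "object"
  },
  "VisitMeta": {
   "additionalProperties": false,
   "description": "Optional visit timings, in minutes.",
   "properties": {
    "minutes_before": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Minutes Before"
    },
    "minutes_during": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Minutes During"
    },
    "minutes_after": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Minutes After"
    }
   },
   "title": "VisitMeta",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "One dwelling visit: per-variable score (0-3) or missing-with-reason.\n\n``entries`` maps each variable id either to an integer score or to a\nmissing-reason code.  The schema forbids extra fields, which is also\nhow personally identifying information is kept out structurally.",
 "properties": {
  "grid_version": {
   "title": "Grid Version",
   "type": "string"
  },
  "entries": {
   "additionalProperties": {
    "anyOf": [
     {
      "type": "integer"
     },
     {
      "type": "string"
     }
    ]
   },
   "title": "Entries",
   "type": "object"
  },
  "dwelling_meta": {
   "$ref": "#/$defs/DwellingMeta"
  },
  "vulnerabilities": {
   "items": {
    "enum": [
     "young_children_u4",
     "elderly_o70",
     "physical_disability",
     "visual_disability",
     "hearing_disability"
    ],
    "type": "string"
   },
   "title": "Vulnerabilities",
   "type": "array",
   "uniqueItems": true
  },
  "visit_meta": {
   "anyOf": [
    {
     "$ref": "#/$defs/VisitMeta"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  }
 },
 "required": [
  "grid_version"
 ],
 "title": "Assessment",
 "type": "object"
}
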