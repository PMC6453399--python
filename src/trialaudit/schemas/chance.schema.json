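{
 "$defs": {
  "ChanceEntry": {
   "properties": {
    "accuracy": {
     "maximum": 1,
     "minimum": 0,
     "title": "Accuracy",
     "type": "number"
    },
    "chance": {
     "exclusiveMaximum": 1,
     "exclusiveMinimum": 0,
     "title": "Chance",
     "type": "number"
    },
    "ci": {
     "items": {
      "type": "number"
     },
     "title": "Ci",
     "type": "array"
    },
    "k": {
     "minimum": 0,
     "title": "K",
     "type": "integer"
    },
    "label": {
     "title": "Label",
     "type": "string"
    },
    "n": {
     "minimum": 1,
     "title": "N",
     "type": "integer"
    },
    "p_value": {
     "maximum": 1,
     "minimum": 0,
     "title": "P Value",
     "type": "number"
    },
    "significant": {
     "title": "Significant",
     "type": "boolean"
    }
   },
   "required": [
    "label",
    "k",
    "n",
    "chance",
    "accuracy",
    "p_value",
    "significant",
    "ci"
   ],
   "title": "ChanceEntry",
   "type": "object"
  }
 },
 "properties": {
  "alpha": {
   "exclusiveMaximum": 1,
   "exclusiveMinimum": 0,
   "title": "Alpha",
   "type": "number"
  },
  "entries": {
   "items": {
    "$ref": "#/$defs/ChanceEntry"
   },
   "title": "Entries",
   "type": "array"
  },
  "schema_version": {
   "title": "Schema Version",
   "type": "integer"
  }
 },
 "required": [
  "schema_version",
  "alpha",
  "entries"
 ],
 "title": "ChanceReport",
 "type": "object"
}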