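{
 "$defs": {
  "MethodReport": {
   "properties": {
    "df": {
     "items": {
      "type": "number"
     },
     "title": "Df",
     "type": "array"
    },
    "grand_mean": {
     "additionalProperties": {
      "items": {
       "type": "number"
      },
      "type": "array"
     },
     "title": "Grand Mean",
     "type": "object"
    },
    "mask": {
     "items": {
      "type": "boolean"
     },
     "title": "Mask",
     "type": "array"
    },
    "n_significant": {
     "minimum": 0,
     "title": "N Significant",
     "type": "integer"
    },
    "n_timepoints": {
     "exclusiveMinimum": 0,
     "title": "N Timepoints",
     "type": "integer"
    },
    "p": {
     "items": {
      "type": "number"
     },
     "title": "P",
     "type": "array"
    },
    "replicate_sd": {
     "additionalProperties": {
      "items": {
       "type": "number"
      },
      "type": "array"
     },
     "title": "Replicate Sd",
     "type": "object"
    },
    "replicate_unit": {
     "title": "Replicate Unit",
     "type": "string"
    },
    "t": {
     "items": {
      "type": "number"
     },
     "title": "T",
     "type": "array"
    }
   },
   "required": [
    "replicate_unit",
    "n_significant",
    "n_timepoints",
    "df",
    "t",
    "p",
    "mask",
    "grand_mean",
    "replicate_sd"
   ],
   "title": "MethodReport",
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
  "correction": {
   "title": "Correction",
   "type": "string"
  },
  "methods": {
   "additionalProperties": {
    "$ref": "#/$defs/MethodReport"
   },
   "title": "Methods",
   "type": "object"
  },
  "schema_version": {
   "title": "Schema Version",
   "type": "integer"
  },
  "time_axis_s": {
   "items": {
    "type": "number"
   },
   "title": "Time Axis S",
   "type": "array"
  }
 },
 "required": [
  "schema_version",
  "alpha",
  "correction",
  "methods",
  "time_axis_s"
 ],
 "title": "AvgStatsReport",
 "type": "object"
}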