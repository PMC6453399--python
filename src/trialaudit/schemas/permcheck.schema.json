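{
 "properties": {
  "audit_alpha": {
   "exclusiveMaximum": 1,
   "exclusiveMinimum": 0,
   "title": "Audit Alpha",
   "type": "number"
  },
  "flagged": {
   "items": {
    "type": "boolean"
   },
   "title": "Flagged",
   "type": "array"
  },
  "fraction_flagged": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "title": "Fraction Flagged"
  },
  "method": {
   "title": "Method",
   "type": "string"
  },
  "n_flagged": {
   "minimum": 0,
   "title": "N Flagged",
   "type": "integer"
  },
  "n_permutations": {
   "minimum": 0,
   "title": "N Permutations",
   "type": "integer"
  },
  "schema_version": {
   "title": "Schema Version",
   "type": "integer"
  },
  "scope": {
   "title": "Scope",
   "type": "string"
  },
  "seed": {
   "title": "Seed",
   "type": "integer"
  },
  "significant_counts": {
   "items": {
    "type": "integer"
   },
   "title": "Significant Counts",
   "type": "array"
  }
 },
 "required": [
  "schema_version",
  "method",
  "scope",
  "n_permutations",
  "audit_alpha",
  "seed",
  "significant_counts",
  "flagged",
  "n_flagged",
  "fraction_flagged"
 ],
 "title": "PermCheckReport",
 "type": "object"
}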