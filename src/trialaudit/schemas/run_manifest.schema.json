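{
 "properties": {
  "figures": {
   "additionalProperties": {
    "type": "string"
   },
   "title": "Figures",
   "type": "object"
  },
  "input": {
   "additionalProperties": true,
   "title": "Input",
   "type": "object"
  },
  "package_version": {
   "title": "Package Version",
   "type": "string"
  },
  "reports": {
   "additionalProperties": {
    "type": "string"
   },
   "title": "Reports",
   "type": "object"
  },
  "schema_version": {
   "title": "Schema Version",
   "type": "integer"
  },
  "seeds": {
   "additionalProperties": {
    "type": "integer"
   },
   "title": "Seeds",
   "type": "object"
  },
  "stages": {
   "items": {
    "type": "string"
   },
   "title": "Stages",
   "type": "array"
  }
 },
 "required": [
  "schema_version",
  "package_version",
  "input",
  "stages",
  "seeds",
  "reports",
  "figures"
 ],
 "title": "RunManifest",
 "type": "object"
}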