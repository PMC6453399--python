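{
 "$defs": {
  "ClassifierReport": {
   "properties": {
    "c_grid": {
     "items": {
      "type": "number"
     },
     "title": "C Grid",
     "type": "array"
    },
    "inner_folds": {
     "minimum": 2,
     "title": "Inner Folds",
     "type": "integer"
    },
    "kernel": {
     "title": "Kernel",
     "type": "string"
    },
    "outer_folds": {
     "minimum": 2,
     "title": "Outer Folds",
     "type": "integer"
    },
    "seed": {
     "title": "Seed",
     "type": "integer"
    }
   },
   "required": [
    "kernel",
    "c_grid",
    "outer_folds",
    "inner_folds",
    "seed"
   ],
   "title": "ClassifierReport",
   "type": "object"
  },
  "DayReport": {
   "properties": {
    "accuracy": {
     "maximum": 1,
     "minimum": 0,
     "title": "Accuracy",
     "type": "number"
    },
    "day_id": {
     "title": "Day Id",
     "type": "string"
    },
    "fold_accuracies": {
     "items": {
      "type": "number"
     },
     "title": "Fold Accuracies",
     "type": "array"
    },
    "k": {
     "minimum": 0,
     "title": "K",
     "type": "integer"
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
    "selected_c": {
     "items": {
      "type": "number"
     },
     "title": "Selected C",
     "type": "array"
    },
    "significant": {
     "title": "Significant",
     "type": "boolean"
    },
    "warnings": {
     "items": {
      "type": "string"
     },
     "title": "Warnings",
     "type": "array"
    }
   },
   "required": [
    "day_id",
    "k",
    "n",
    "accuracy",
    "fold_accuracies",
    "selected_c",
    "p_value",
    "significant",
    "warnings"
   ],
   "title": "DayReport",
   "type": "object"
  },
  "FeatureSpecReport": {
   "properties": {
    "baseline_correct": {
     "title": "Baseline Correct",
     "type": "boolean"
    },
    "baseline_window_s": {
     "items": {
      "type": "number"
     },
     "title": "Baseline Window S",
     "type": "array"
    },
    "representation": {
     "title": "Representation",
     "type": "string"
    },
    "response_window_s": {
     "items": {
      "type": "number"
     },
     "title": "Response Window S",
     "type": "array"
    }
   },
   "required": [
    "representation",
    "baseline_window_s",
    "response_window_s",
    "baseline_correct"
   ],
   "title": "FeatureSpecReport",
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
  "chance": {
   "exclusiveMaximum": 1,
   "exclusiveMinimum": 0,
   "title": "Chance",
   "type": "number"
  },
  "classifier": {
   "$ref": "#/$defs/ClassifierReport"
  },
  "days": {
   "items": {
    "$ref": "#/$defs/DayReport"
   },
   "title": "Days",
   "type": "array"
  },
  "feature_spec": {
   "$ref": "#/$defs/FeatureSpecReport"
  },
  "mean_accuracy": {
   "maximum": 1,
   "minimum": 0,
   "title": "Mean Accuracy",
   "type": "number"
  },
  "n_significant_days": {
   "minimum": 0,
   "title": "N Significant Days",
   "type": "integer"
  },
  "schema_version": {
   "title": "Schema Version",
   "type": "integer"
  }
 },
 "required": [
  "schema_version",
  "chance",
  "alpha",
  "feature_spec",
  "classifier",
  "days",
  "mean_accuracy",
  "n_significant_days"
 ],
 "title": "ClassifyReport",
 "type": "object"
}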