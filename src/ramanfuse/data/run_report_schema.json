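{
  "$defs": {
    "GroupResult": {
      "description": "Selected model + metrics for one (biofluid, state) analysis group.",
      "properties": {
        "biofluid": {
          "title": "Biofluid",
          "type": "string"
        },
        "state": {
          "title": "State",
          "type": "string"
        },
        "n_patients": {
          "title": "N Patients",
          "type": "integer"
        },
        "flavor": {
          "title": "Flavor",
          "type": "string"
        },
        "pc_subset": {
          "title": "Pc Subset",
          "type": "string"
        },
        "cv": {
          "$ref": "#/$defs/Metrics"
        },
        "resubstitution": {
          "$ref": "#/$defs/Metrics"
        },
        "cv_auc": {
          "title": "Cv Auc",
          "type": "number"
        }
      },
      "required": [
        "biofluid",
        "state",
        "n_patients",
        "flavor",
        "pc_subset",
        "cv",
        "resubstitution",
        "cv_auc"
      ],
      "title": "GroupResult",
      "type": "object"
    },
    "Metrics": {
      "properties": {
        "tp": {
          "title": "Tp",
          "type": "integer"
        },
        "fp": {
          "title": "Fp",
          "type": "integer"
        },
        "tn": {
          "title": "Tn",
          "type": "integer"
        },
        "fn": {
          "title": "Fn",
          "type": "integer"
        },
        "sensitivity": {
          "title": "Sensitivity",
          "type": "number"
        },
        "specificity": {
          "title": "Specificity",
          "type": "number"
        },
        "accuracy": {
          "title": "Accuracy",
          "type": "number"
        }
      },
      "required": [
        "tp",
        "fp",
        "tn",
        "fn",
        "sensitivity",
        "specificity",
        "accuracy"
      ],
      "title": "Metrics",
      "type": "object"
    },
    "StageCounts": {
      "properties": {
        "spectra_loaded": {
          "title": "Spectra Loaded",
          "type": "integer"
        },
        "spectra_dropped": {
          "title": "Spectra Dropped",
          "type": "integer"
        },
        "spectra_kept": {
          "title": "Spectra Kept",
          "type": "integer"
        },
        "patients": {
          "title": "Patients",
          "type": "integer"
        },
        "fused": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Fused",
          "type": "object"
        }
      },
      "required": [
        "spectra_loaded",
        "spectra_dropped",
        "spectra_kept",
        "patients"
      ],
      "title": "StageCounts",
      "type": "object"
    }
  },
  "properties": {
    "version": {
      "title": "Version",
      "type": "string"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "counts": {
      "$ref": "#/$defs/StageCounts"
    },
    "results": {
      "items": {
        "$ref": "#/$defs/GroupResult"
      },
      "title": "Results",
      "type": "array"
    },
    "skipped": {
      "items": {
        "type": "string"
      },
      "title": "Skipped",
      "type": "array"
    },
    "output_files": {
      "items": {
        "type": "string"
      },
      "title": "Output Files",
      "type": "array"
    }
  },
  "required": [
    "version",
    "config",
    "counts",
    "results"
  ],
  "title": "RunReport",
  "type": "object"
}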