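{
  "$defs": {
    "CandidateEntry": {
      "properties": {
        "chrom": {
          "title": "Chrom",
          "type": "string"
        },
        "end": {
          "title": "End",
          "type": "integer"
        },
        "fc": {
          "title": "Fc",
          "type": "number"
        },
        "gene_id": {
          "title": "Gene Id",
          "type": "string"
        },
        "log10fc": {
          "title": "Log10Fc",
          "type": "number"
        },
        "p": {
          "title": "P",
          "type": "number"
        },
        "passes": {
          "title": "Passes",
          "type": "boolean"
        },
        "start": {
          "title": "Start",
          "type": "integer"
        },
        "window": {
          "title": "Window",
          "type": "string"
        }
      },
      "required": [
        "window",
        "gene_id",
        "chrom",
        "start",
        "end",
        "fc",
        "log10fc",
        "p",
        "passes"
      ],
      "title": "CandidateEntry",
      "type": "object"
    },
    "FishCallEntry": {
      "properties": {
        "call": {
          "title": "Call",
          "type": "string"
        },
        "fusion_positive": {
          "title": "Fusion Positive",
          "type": "integer"
        },
        "gain_or_break": {
          "title": "Gain Or Break",
          "type": "integer"
        },
        "n_cells_scored": {
          "title": "N Cells Scored",
          "type": "integer"
        },
        "n_informative": {
          "title": "N Informative",
          "type": "integer"
        },
        "normal": {
          "title": "Normal",
          "type": "integer"
        },
        "probe_set": {
          "title": "Probe Set",
          "type": "string"
        },
        "sample_id": {
          "title": "Sample Id",
          "type": "string"
        },
        "uninformative": {
          "title": "Uninformative",
          "type": "integer"
        }
      },
      "required": [
        "sample_id",
        "probe_set",
        "n_cells_scored",
        "n_informative",
        "normal",
        "gain_or_break",
        "fusion_positive",
        "uninformative",
        "call"
      ],
      "title": "FishCallEntry",
      "type": "object"
    },
    "RecurrenceEntry": {
      "properties": {
        "aberration": {
          "title": "Aberration",
          "type": "string"
        },
        "count": {
          "title": "Count",
          "type": "integer"
        },
        "per_karyotype": {
          "items": {
            "type": "integer"
          },
          "title": "Per Karyotype",
          "type": "array"
        },
        "total_occurrences": {
          "title": "Total Occurrences",
          "type": "integer"
        }
      },
      "required": [
        "aberration",
        "count",
        "total_occurrences",
        "per_karyotype"
      ],
      "title": "RecurrenceEntry",
      "type": "object"
    },
    "TruthMetrics": {
      "properties": {
        "expression_n_detectable": {
          "title": "Expression N Detectable",
          "type": "integer"
        },
        "expression_sensitivity": {
          "title": "Expression Sensitivity",
          "type": "number"
        },
        "expression_sign_agreement": {
          "title": "Expression Sign Agreement",
          "type": "number"
        },
        "fish_correct_calls": {
          "title": "Fish Correct Calls",
          "type": "integer"
        },
        "fish_n_samples": {
          "title": "Fish N Samples",
          "type": "integer"
        },
        "karyotype_expected_carriers": {
          "title": "Karyotype Expected Carriers",
          "type": "integer"
        },
        "karyotype_observed_count": {
          "title": "Karyotype Observed Count",
          "type": "integer"
        }
      },
      "required": [
        "karyotype_expected_carriers",
        "karyotype_observed_count",
        "fish_correct_calls",
        "fish_n_samples",
        "expression_sensitivity",
        "expression_sign_agreement",
        "expression_n_detectable"
      ],
      "title": "TruthMetrics",
      "type": "object"
    }
  },
  "description": "Schema of the structured JSON report written by :func:`run_demo`.",
  "properties": {
    "candidates": {
      "items": {
        "$ref": "#/$defs/CandidateEntry"
      },
      "title": "Candidates",
      "type": "array"
    },
    "fish_calls": {
      "items": {
        "$ref": "#/$defs/FishCallEntry"
      },
      "title": "Fish Calls",
      "type": "array"
    },
    "parameters": {
      "additionalProperties": true,
      "title": "Parameters",
      "type": "object"
    },
    "recurrence": {
      "items": {
        "$ref": "#/$defs/RecurrenceEntry"
      },
      "title": "Recurrence",
      "type": "array"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "truth_metrics": {
      "$ref": "#/$defs/TruthMetrics"
    }
  },
  "required": [
    "seed",
    "parameters",
    "recurrence",
    "fish_calls",
    "candidates",
    "truth_metrics"
  ],
  "title": "DemoReport",
  "type": "object"
}
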