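{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "crcea model-inputs document",
  "description": "Declarative inputs for the Stage I/II colorectal-cancer adjuvant-therapy models. A 'common' block holds shared settings; 'stage_I' and 'stage_II' blocks select strategies and stage-specific utilities/PSA sets.",
  "type": "object",
  "required": ["common", "stage_I", "stage_II"],
  "properties": {
    "common": {
      "type": "object",
      "required": [
        "start_age", "horizon", "cohort_size", "wtp", "discount",
        "cpi_medical_2013", "cost_items", "surveillance_schedules",
        "indirect_cost_years", "aspirin_ae_events", "strategies"
      ],
      "properties": {
        "start_age": {"type": "integer", "minimum": 0},
        "horizon": {"type": "integer", "minimum": 1},
        "cohort_size": {"type": "number", "exclusiveMinimum": 0},
        "wtp": {"type": "number", "minimum": 0},
        "discount": {
          "type": "object",
          "required": ["cost_rate", "outcome_rate"],
          "properties": {
            "cost_rate": {"type": "number", "minimum": 0},
            "outcome_rate": {"type": "number", "minimum": 0}
          }
        },
        "cpi_medical_2013": {
          "type": "object",
          "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
        },
        "cost_items": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["raw", "year"],
            "properties": {
              "raw": {"type": "number", "minimum": 0},
              "year": {"type": "integer"},
              "unit": {"enum": ["per_year", "per_month", "per_episode", "per_admin"]},
              "printed": {"type": "number", "minimum": 0},
              "note": {"type": "string"}
            }
          }
        },
        "surveillance_schedules": {
          "type": "object",
          "required": [
            "physician_visits_per_year", "blood_tests_per_year",
            "cea_tests_per_year", "ct_scans_per_year", "colonoscopy_years"
          ],
          "additionalProperties": {
            "type": "array", "items": {"type": "number", "minimum": 0}
          }
        },
        "indirect_cost_years": {"type": "integer", "minimum": 0},
        "aspirin_ae_events": {
          "type": "object",
          "required": ["nonfatal", "fatal"],
          "additionalProperties": {
            "type": "object",
            "additionalProperties": {
              "type": "object",
              "required": ["p65", "p85", "cost", "year"],
              "properties": {
                "p65": {"type": "number", "minimum": 0, "maximum": 1},
                "p85": {"type": "number", "minimum": 0, "maximum": 1},
                "cost": {"type": "number", "minimum": 0},
                "year": {"type": "integer"}
              }
            }
          }
        },
        "strategies": {"type": "object"}
      }
    },
    "stage_I": {"$ref": "#/$defs/stage"},
    "stage_II": {"$ref": "#/$defs/stage"}
  },
  "$defs": {
    "stage": {
      "type": "object",
      "required": ["strategies", "utilities"],
      "properties": {
        "strategies": {
          "type": "array",
          "items": {"enum": ["aspirin", "capecitabine", "no_treatment"]},
          "minItems": 2
        },
        "utilities": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["value"],
            "properties": {
              "value": {"type": "number", "minimum": 0, "maximum": 1},
              "sa_range": {
                "type": "array",
                "items": {"type": "number", "minimum": 0, "maximum": 1},
                "minItems": 2, "maxItems": 2
              }
            }
          }
        },
        "psa_parameters": {"type": "array", "items": {"type": "string"}}
      }
    }
  }
}
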