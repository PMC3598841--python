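{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "fabrycea parameter file",
  "description": "Layout of the YAML parameter files consumed by fabrycea.parameters.load_parameter_file. The loader enforces these rules directly on load.",
  "type": "object",
  "required": ["transitions", "utilities", "costs", "treatment_effect", "simulation"],
  "$defs": {
    "probability": {
      "oneOf": [
        {"type": "number", "minimum": 0, "maximum": 1},
        {
          "type": "object",
          "required": ["p"],
          "properties": {
            "p": {"type": "number", "minimum": 0, "maximum": 1},
            "lcl": {"type": "number", "minimum": 0, "maximum": 1},
            "ucl": {"type": "number", "minimum": 0, "maximum": 1},
            "alpha": {"type": "number", "exclusiveMinimum": 0},
            "beta": {"type": "number", "exclusiveMinimum": 0},
            "median_unreached": {"type": "boolean"}
          }
        }
      ]
    },
    "by_sex": {
      "type": "object",
      "required": ["male", "female"],
      "properties": {
        "male": {"$ref": "#/$defs/probability"},
        "female": {"$ref": "#/$defs/probability"}
      }
    }
  },
  "properties": {
    "states": {
      "type": "array",
      "items": {"type": "string"},
      "description": "optional restatement of the 11 model states; checked against the model"
    },
    "transitions": {
      "type": "object",
      "description": "keys are 'from->to' edges of the transition graph plus a 'death' block; values are per-sex annual probabilities",
      "properties": {
        "death": {
          "type": "object",
          "description": "'any' for a shared death probability or one entry per state",
          "additionalProperties": {"$ref": "#/$defs/by_sex"}
        }
      },
      "additionalProperties": {"$ref": "#/$defs/by_sex"}
    },
    "utilities": {
      "type": "object",
      "description": "per-cluster utility per year in [0,1] with optional 95% CI",
      "required": ["asymptomatic", "acro_or_symptoms", "single_complication", "multiple_complications"]
    },
    "costs": {
      "type": "object",
      "required": ["state"],
      "properties": {
        "ert_per_year": {"type": "number", "minimum": 0},
        "unit_cost_hour": {"type": "number", "minimum": 0},
        "state": {"type": "object", "description": "EUR per year per cluster"},
        "state_overrides": {"type": "object", "description": "EUR per year per individual state"},
        "production_loss": {"type": "object", "description": "EUR per year per cluster"}
      }
    },
    "treatment_effect": {
      "type": "object",
      "required": ["or_first", "or_second"],
      "properties": {
        "or_first": {"description": "odds ratio per treatment-year, symptoms -> first complication"},
        "or_second": {"description": "odds ratio per treatment-year, first -> second complication"},
        "median_duration_symptoms": {"type": "number", "exclusiveMinimum": 0},
        "median_duration_single_complication": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "discounting": {
      "type": "object",
      "properties": {
        "effects": {"type": "number", "minimum": 0},
        "costs": {"type": "number", "minimum": 0},
        "mode": {"enum": ["none", "differential"]}
      }
    },
    "simulation": {
      "type": "object",
      "properties": {
        "horizon": {"type": "integer", "minimum": 1},
        "cycle_length": {"type": "number", "exclusiveMinimum": 0},
        "sex_mix": {"type": "number", "minimum": 0, "maximum": 1},
        "ert_start_rule": {"enum": ["at-symptoms", "at-age-40", "never", "stop-after-2-complications"]},
        "wtp_min": {"type": "number", "exclusiveMinimum": 0},
        "wtp_max": {"type": "number", "exclusiveMinimum": 0},
        "wtp_points": {"type": "integer", "minimum": 2},
        "wtp_grid": {"type": "array", "items": {"type": "number"}},
        "life_table": {"type": "string", "description": "path to an age,sex,qx CSV; default: bundled synthetic table"}
      }
    },
    "metadata": {"type": "object"}
  }
}
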