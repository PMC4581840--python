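{
  "schema_version": "1.0",
  "description": "Column dictionary for kg7screen cohort CSV tables. One row per patient; comma-separated, UTF-8, '.' decimal. Empty cell or 'NA' = missing (unassessed); 'NC' = observed not-capable response.",
  "columns": {
    "patient_id": {"type": "string", "required": true, "unique": true},
    "age": {"type": "integer", "range": [0, 130], "unit": "years"},
    "sex": {"type": "enum", "values": ["male", "female"]},
    "adl_*": {
      "type": "number",
      "items": {
        "feeding": 10, "bathing": 5, "grooming": 5, "dressing": 10,
        "bowels": 10, "bladder": 10, "toilet_use": 10, "transfers": 15,
        "walking": 15, "stairs": 10
      },
      "note": "Barthel item scores; value = points retained (max listed); total 0-100"
    },
    "iadl_*": {
      "type": "enum",
      "values": ["independent", "dependent", "NC"],
      "items_all": ["telephone", "shopping", "transportation", "medication", "finances",
                    "food_preparation", "laundry", "housekeeping"],
      "note": "Lawton-Brody items; the last three apply to women only"
    },
    "mmse_*": {
      "type": "integer",
      "items": {
        "orientation_time_date": 3, "orientation_time_other": 2,
        "orientation_place": 5, "registration": 3, "attention_calculation": 5,
        "recall": 3, "language": 6, "complex_commands": 3
      },
      "note": "MMSE-KC component sub-scores; total 0-30"
    },
    "mmse_nc": {"type": "flag", "values": ["", "NC"]},
    "sgds_*": {
      "type": "integer", "range": [0, 1],
      "items_all": ["satisfied_with_life", "dropped_activities", "life_empty",
                    "often_bored", "good_spirits", "afraid_bad_things",
                    "happy_most_time", "feel_helpless", "prefer_stay_home",
                    "memory_problems", "wonderful_to_be_alive", "feel_worthless",
                    "full_of_energy", "situation_hopeless", "others_better_off"],
      "note": "1 = depressive response; total 0-15"
    },
    "sgds_nc": {"type": "flag", "values": ["", "NC"]},
    "mna_*": {
      "type": "number",
      "items": {
        "food_intake_decline": 2, "weight_loss": 3, "mobility": 2,
        "psych_stress": 2, "neuropsych_problems": 2, "bmi": 3,
        "lives_independently": 1, "more_than_3_drugs": 1, "pressure_sores": 1,
        "full_meals": 2, "protein_intake": 1, "fruits_vegetables": 1,
        "fluid_intake": 1, "feeding_mode": 2, "self_view_nutrition": 2,
        "health_comparison": 2, "mid_arm_circumference": 1, "calf_circumference": 1
      },
      "note": "MNA item points (max listed, some items in 0.5 steps); total 0-30"
    },
    "mna_nc": {"type": "flag", "values": ["", "NC"]},
    "tgug_seconds": {"type": "number_or_NC", "range": [0, null], "unit": "seconds"},
    "charlson_points": {"type": "integer", "range": [0, null]},
    "n_drugs": {"type": "integer", "range": [0, null]},
    "os_time": {"type": "number", "range": [0, null], "unit": "days"},
    "os_event": {"type": "enum", "values": ["death", "censored"]}
  }
}
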