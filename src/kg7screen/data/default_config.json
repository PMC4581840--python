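{
  "selection": {
    "se_thresholds": [0.90, 0.80],
    "items_per_domain": 2,
    "feasibility_exclusions": {
      "mmse_attention_calculation": "not feasible in an outpatient setting",
      "mmse_recall": "not feasible in an outpatient setting",
      "mmse_complex_commands": "low feasibility",
      "mna_health_comparison": "not suitable for cancer patients",
      "mna_psych_stress": "not suitable for recently diagnosed cancer patients"
    }
  },
  "thresholds": {
    "adl_severe_max_total": 75,
    "iadl_severe_max_independent": {"male": 3, "female": 6},
    "mmse": {"severe_max": 16, "mild_max": 24},
    "sgds": {"severe_min": 10, "mild_min": 5},
    "mna": {"severe_below": 17, "intact_from": 24},
    "tgug": {"deficit_over_seconds": 20, "severe_from_seconds": 25},
    "charlson_bands": {"low": [0, 0], "medium": [1, 2], "high": [3, 4], "very_high": [5, null]}
  },
  "reference": {
    "abnormal_min_deficits": 2,
    "domains": ["ADL", "IADL", "MMSE", "SGDS", "MNA", "TGUG"]
  },
  "cutoff_selection": {"min_sensitivity": 0.90}
}
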