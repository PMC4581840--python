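{
  "kg7": {
    "name": "KG-7",
    "score_range": [0, 7],
    "abnormal_rule": {"comparator": "<=", "cutoff": 5},
    "items": [
      {
        "item_id": "shower_bath",
        "question": "Can you take a shower or bath without help?",
        "responses": ["yes", "no"],
        "points": {"yes": 1, "no": 0}
      },
      {
        "item_id": "ascend_stairs",
        "question": "Can you ascend the stairs without help?",
        "responses": ["yes", "no"],
        "points": {"yes": 1, "no": 0}
      },
      {
        "item_id": "shopping",
        "question": "Can you take care of all shopping needs independently?",
        "responses": ["yes", "no"],
        "points": {"yes": 1, "no": 0}
      },
      {
        "item_id": "nutrition_self_view",
        "question": "How is the self-view of your nutritional status?",
        "responses": ["good", "bad"],
        "points": {"good": 1, "bad": 0}
      },
      {
        "item_id": "over_3_drugs",
        "question": "Do you take more than 3 prescription drugs per day?",
        "responses": ["no", "yes"],
        "points": {"no": 1, "yes": 0}
      },
      {
        "item_id": "date_orientation",
        "question": "What year, month and day is this?",
        "responses": ["correct", "incorrect"],
        "points": {"correct": 1, "incorrect": 0}
      },
      {
        "item_id": "dropped_activities",
        "question": "Have you dropped many of your activities and interests?",
        "responses": ["no", "yes"],
        "points": {"no": 1, "yes": 0}
      }
    ]
  },
  "g8": {
    "name": "G-8",
    "score_range": [0, 17],
    "abnormal_rule": {"comparator": "<=", "cutoff": 14},
    "items": [
      {"item_id": "food_intake_decline", "source": "mna", "points": [0, 1, 2]},
      {"item_id": "weight_loss", "source": "mna", "points": [0, 1, 2, 3]},
      {"item_id": "mobility", "source": "mna", "points": [0, 1, 2]},
      {"item_id": "neuropsych_problems", "source": "mna", "points": [0, 1, 2]},
      {"item_id": "bmi", "source": "mna", "points": [0, 1, 2, 3]},
      {"item_id": "more_than_3_drugs", "source": "mna", "points": [0, 1]},
      {"item_id": "health_comparison", "source": "mna", "points": [0, 0.5, 1, 2]},
      {"item_id": "age", "source": "age", "bands": [[86, 999, 0], [80, 85, 1], [0, 79, 2]]}
    ]
  }
}
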