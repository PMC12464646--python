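{
  "classification_systems": {
    "question": "Preferred patient classification system (Delphi 1, round 2)",
    "n_rankers": 29,
    "n_ranks": 3,
    "options": {
      "traffic_light": {"label": "Traffic light (red, amber and green)", "counts": [17, 11, 1]},
      "levels_1_4": {"label": "Levels (1-4)", "counts": [11, 11, 8]},
      "high_risk_only": {"label": "Only high-risk indicators", "counts": [1, 7, 20]}
    }
  },
  "review_frequency": {
    "question": "Preferred frequency of pharmacy review per risk category (Delphi 2, round 2)",
    "red": {
      "n_rankers": 29,
      "n_ranks": 3,
      "options": {
        "daily": {"label": "Daily", "counts": [6, 3, 20]},
        "every_1_2_days": {"label": "Every 1-2 days", "counts": [12, 17, 0]},
        "three_times_a_week": {"label": "3 times a week", "counts": [11, 9, 9]}
      }
    },
    "amber": {
      "n_rankers": 29,
      "n_ranks": 4,
      "options": {
        "every_1_2_days": {"label": "Every 1-2 days", "counts": [3, 3, 4, 19]},
        "every_2_3_days": {"label": "Every 2-3 days", "counts": [4, 11, 12, 2]},
        "every_2_4_days": {"label": "Every 2-4 days", "counts": [11, 8, 9, 1]},
        "twice_a_week": {"label": "Twice a week", "counts": [11, 7, 4, 7]}
      }
    },
    "green": {
      "n_rankers": 29,
      "n_ranks": 3,
      "options": {
        "weekly_or_referral": {"label": "Once every working week or more frequently based on referral", "counts": [19, 10, 0]},
        "every_3_7_days": {"label": "Every 3-7 days or upon referral", "counts": [9, 18, 2]},
        "every_14_days": {"label": "Every 14 days or upon referral", "counts": [1, 1, 27]}
      }
    }
  }
}
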