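{
  "n_public_clonotypes": 2,
  "reference_condition": "vehicle_only",
  "subjects": {
    "S01": {
      "antigen_set_distribution": {
        "G12A": 4,
        "G12A+G12C+G12R": 1,
        "G12A+G12D": 1,
        "G12A+G12R": 1,
        "G12C": 3,
        "G12C+G12D": 1,
        "G12D": 1,
        "G12D+G12V+G13D": 1,
        "G12R": 2,
        "G12V": 3,
        "G13D": 4
      },
      "n_calls": 25,
      "n_cross_reactive": 5,
      "n_expanded_per_antigen": {
        "G12A": 7,
        "G12C": 5,
        "G12D": 4,
        "G12R": 5,
        "G12V": 6,
        "G13D": 5
      },
      "n_filtered_by_baseline": 3,
      "n_specific": 22,
      "skipped_conditions": [],
      "tumor_overlap": {
        "count": 8,
        "fraction": 0.36363636363636365,
        "per_antigen": {
          "G12A": 4,
          "G12C": 1,
          "G12D": 1,
          "G12R": 1,
          "G12V": 1,
          "G13D": 1
        }
      }
    },
    "S02": {
      "antigen_set_distribution": {
        "G12A": 5,
        "G12A+G12C": 1,
        "G12A+G12C+G12R": 1,
        "G12A+G12V": 1,
        "G12A+G13D": 1,
        "G12C": 1,
        "G12C+G12V": 1,
        "G12C+G13D": 1,
        "G12D": 2,
        "G12D+G12V": 1,
        "G12R": 4,
        "G12V": 2,
        "G13D": 1
      },
      "n_calls": 25,
      "n_cross_reactive": 7,
      "n_expanded_per_antigen": {
        "G12A": 9,
        "G12C": 5,
        "G12D": 4,
        "G12R": 5,
        "G12V": 6,
        "G13D": 4
      },
      "n_filtered_by_baseline": 3,
      "n_specific": 22,
      "skipped_conditions": [],
      "tumor_overlap": {
        "count": 8,
        "fraction": 0.36363636363636365,
        "per_antigen": {
          "G12A": 1,
          "G12C": 4,
          "G12D": 2,
          "G12R": 1,
          "G12V": 1,
          "G13D": 2
        }
      }
    },
    "S03": {
      "antigen_set_distribution": {
        "G12A": 5,
        "G12C": 2,
        "G12C+G12V": 1,
        "G12C+G13D": 1,
        "G12D": 3,
        "G12D+G12V": 1,
        "G12R": 4,
        "G12V": 4,
        "G13D": 2
      },
      "n_calls": 26,
      "n_cross_reactive": 3,
      "n_expanded_per_antigen": {
        "G12A": 5,
        "G12C": 6,
        "G12D": 4,
        "G12R": 4,
        "G12V": 6,
        "G13D": 4
      },
      "n_filtered_by_baseline": 3,
      "n_specific": 23,
      "skipped_conditions": [],
      "tumor_overlap": {
        "count": 8,
        "fraction": 0.34782608695652173,
        "per_antigen": {
          "G12A": 2,
          "G12C": 1,
          "G12D": 1,
          "G12R": 2,
          "G12V": 2,
          "G13D": 1
        }
      }
    }
  }
}
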