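{
  "acquisition": {
    "clade_fraction_pct": {
      "Amniota": 54.5,
      "Simiiformes": 45.5
    },
    "n_capped": 0,
    "n_sites": 55
  },
  "config_hash": "9453f57b46aa",
  "enrichment": {
    "ESC": {
      "n_tested": 3,
      "significant": [
        "AmnSINE-X"
      ]
    },
    "NPC": {
      "n_tested": 3,
      "significant": [
        "AmnSINE-X",
        "MERS1A"
      ]
    }
  },
  "expression": {
    "ESC": {
      "down": 0,
      "n_links": 5,
      "strong_down": 0,
      "strong_ratio": "inf",
      "strong_up": 2,
      "up": 5,
      "up_down_ratio": "inf"
    },
    "NPC": {
      "down": 6,
      "n_links": 30,
      "strong_down": 0,
      "strong_ratio": "inf",
      "strong_up": 13,
      "up": 24,
      "up_down_ratio": 4.0
    }
  },
  "function": {
    "ESC": {
      "cisreg_fraction_pct": 86.7,
      "control_fraction_pct": 8.9,
      "n_te_sites": 15,
      "p_binomial": 0.0
    },
    "ESC_specific_transition": {
      "n_sites": 5,
      "row_fractions": {
        "cis-regulatory": {
          "cis-regulatory": 0.25,
          "heterochromatin": 0.0,
          "other": 0.0,
          "quiescent/low": 0.75,
          "transcription": 0.0
        },
        "heterochromatin": {
          "cis-regulatory": 0.0,
          "heterochromatin": 0.0,
          "other": 0.0,
          "quiescent/low": 0.0,
          "transcription": 0.0
        },
        "other": {
          "cis-regulatory": 0.0,
          "heterochromatin": 0.0,
          "other": 0.0,
          "quiescent/low": 0.0,
          "transcription": 0.0
        },
        "quiescent/low": {
          "cis-regulatory": 1.0,
          "heterochromatin": 0.0,
          "other": 0.0,
          "quiescent/low": 0.0,
          "transcription": 0.0
        },
        "transcription": {
          "cis-regulatory": 0.0,
          "heterochromatin": 0.0,
          "other": 0.0,
          "quiescent/low": 0.0,
          "transcription": 0.0
        }
      }
    },
    "NPC": {
      "cisreg_fraction_pct": 90.0,
      "control_fraction_pct": 8.8,
      "n_te_sites": 40,
      "p_binomial": 0.0
    },
    "NPC_specific_transition": {
      "n_sites": 30,
      "row_fractions": {
        "cis-regulatory": {
          "cis-regulatory": 0.0769,
          "heterochromatin": 0.0,
          "other": 0.0,
          "quiescent/low": 0.8462,
          "transcription": 0.0769
        },
        "heterochromatin": {
          "cis-regulatory": 0.0,
          "heterochromatin": 1.0,
          "other": 0.0,
          "quiescent/low": 0.0,
          "transcription": 0.0
        },
        "other": {
          "cis-regulatory": 0.0,
          "heterochromatin": 0.0,
          "other": 0.0,
          "quiescent/low": 0.0,
          "transcription": 0.0
        },
        "quiescent/low": {
          "cis-regulatory": 0.0,
          "heterochromatin": 0.5,
          "other": 0.0,
          "quiescent/low": 0.5,
          "transcription": 0.0
        },
        "transcription": {
          "cis-regulatory": 0.0,
          "heterochromatin": 0.0,
          "other": 0.0,
          "quiescent/low": 1.0,
          "transcription": 0.0
        }
      }
    },
    "conservation": {
      "df": 45.02034,
      "mean_control": 0.3018,
      "mean_sites": 0.311314,
      "p": 0.0,
      "t": 29.893712
    }
  },
  "overlap": {
    "ESC": {
      "class_composition_pct": {
        "SINE": 20.0
      },
      "te_assigned": 15,
      "te_fraction_pct": 20.0,
      "total_summits": 75
    },
    "NPC": {
      "class_composition_pct": {
        "LTR": 25.0,
        "SINE": 15.0
      },
      "te_assigned": 40,
      "te_fraction_pct": 40.0,
      "total_summits": 100
    },
    "shared_te_copies": {
      "a_only": 5,
      "b_only": 30,
      "shared": 10
    }
  },
  "propagation_candidates": {
    "ESC": [
      "AmnSINE-X"
    ],
    "NPC": [
      "AmnSINE-X",
      "MERS1A"
    ]
  },
  "seed": 11
}
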