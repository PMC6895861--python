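{
  "type": "object",
  "required": ["provenance", "scores_file", "coverage", "ranking", "multiple_testing_correction"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package", "version", "seed", "config_hash"],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "seed": {"type": "integer"},
        "config_hash": {"type": "string"}
      }
    },
    "scores_file": {"type": "string"},
    "coverage": {"type": "object"},
    "ranking": {
      "type": "object",
      "required": ["signature", "threshold", "order", "labels"],
      "properties": {
        "signature": {"type": "string"},
        "threshold": {"type": "number"},
        "order": {"type": "array", "items": {"type": "string"}},
        "labels": {"type": "object"}
      }
    },
    "correlations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["signatures", "r", "n", "p"],
        "properties": {
          "signatures": {"type": "array", "items": {"type": "string"}},
          "r": {"type": "number"},
          "n": {"type": "integer"},
          "p": {"type": "number"}
        }
      }
    },
    "exclusivity": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["genes", "table", "odds_ratio", "p", "co_occurrence", "exclusive"],
        "properties": {
          "genes": {"type": "array", "items": {"type": "string"}},
          "table": {"type": "array"},
          "odds_ratio": {"type": ["number", "string", "null"]},
          "p": {"type": "number"},
          "co_occurrence": {"type": "integer"},
          "exclusive": {"type": "boolean"}
        }
      }
    },
    "group_comparisons": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["score", "grouping", "groups", "mean_a", "mean_b", "n_a", "n_b", "t", "p"],
        "properties": {
          "score": {"type": "string"},
          "grouping": {"type": "string"},
          "groups": {"type": "array", "items": {"type": "string"}},
          "mean_a": {"type": "number"},
          "mean_b": {"type": "number"},
          "n_a": {"type": "integer"},
          "n_b": {"type": "integer"},
          "t": {"type": "number"},
          "p": {"type": "number"}
        }
      }
    },
    "survival": {
      "type": "object",
      "properties": {
        "geometric_mean_split": {
          "type": "object",
          "required": ["gene", "sizes", "medians", "logrank"],
          "properties": {
            "gene": {"type": "string"},
            "sizes": {"type": "object"},
            "medians": {"type": "object"},
            "logrank": {
              "type": "object",
              "required": ["statistic", "p"],
              "properties": {
                "statistic": {"type": "number"},
                "p": {"type": "number"}
              }
            }
          }
        },
        "quadrant": {
          "type": "object",
          "required": ["scores", "sizes", "logrank"],
          "properties": {
            "scores": {"type": "array", "items": {"type": "string"}},
            "sizes": {"type": "object"},
            "logrank": {
              "type": "object",
              "required": ["statistic", "p"],
              "properties": {
                "statistic": {"type": "number"},
                "p": {"type": "number"}
              }
            }
          }
        }
      }
    },
    "multiple_testing_correction": {"type": "string", "enum": ["none"]}
  }
}
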