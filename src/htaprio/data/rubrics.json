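{
  "criteria_order": [
    "efficiency_effectiveness",
    "safety",
    "population_size",
    "vulnerable_population",
    "alternatives_availability",
    "cost_effectiveness",
    "budget_impact",
    "financial_protection",
    "evidence_quality"
  ],
  "efficiency_effectiveness": {
    "treatment_labels": {
      "perfect treatment": 5,
      "lifetime increasing and major improvement of quality of life": 4,
      "lifetime increasing and low improvement of quality of life": 3,
      "major improvement of quality of life": 2,
      "low improvement of quality of life": 1
    },
    "screening": {"high_accuracy": 80.0, "low_accuracy": 60.0},
    "prevention_bands": [
      {"op": "gt", "value": 90.0, "code": 5},
      {"op": "gt", "value": 80.0, "code": 4},
      {"op": "gt", "value": 70.0, "code": 3},
      {"op": "gt", "value": 60.0, "code": 2}
    ],
    "prevention_else": 1
  },
  "safety": {
    "levels": {
      "completely safe": 5,
      "relatively safe": 4,
      "proper safety": 3,
      "poor safety": 2,
      "unsafe": 1
    },
    "bands": [
      {"op": "lt", "value": 1.0, "code": 5},
      {"op": "lt", "value": 10.0, "code": 4},
      {"op": "lt", "value": 40.0, "code": 3},
      {"op": "le", "value": 50.0, "code": 2}
    ],
    "else": 1
  },
  "population_size": {
    "bands": [
      {"op": "gt", "value": 500000, "code": 5},
      {"op": "gt", "value": 100000, "code": 4},
      {"op": "gt", "value": 50000, "code": 3},
      {"op": "gt", "value": 10000, "code": 2}
    ],
    "else": 1
  },
  "vulnerable_population": {
    "bands": [
      {"op": "gt", "value": 50.0, "code": 5},
      {"op": "gt", "value": 25.0, "code": 4},
      {"op": "gt", "value": 10.0, "code": 3}
    ],
    "else": 2,
    "unspecified": 1
  },
  "alternatives_availability": {
    "levels": {
      "partial": 5,
      "relatively appropriate": 4,
      "appropriate": 3,
      "high": 2,
      "very high": 1
    }
  },
  "evidence_quality": {
    "categories": {
      "systematic-review-rct-high": 5,
      "hta-high": 5,
      "systematic-review-rct-medium-low": 4,
      "hta-medium-low": 4,
      "rct-high": 3,
      "cct-high": 3,
      "systematic-review-other-high": 3,
      "rct-medium-low": 2,
      "cct-medium-low": 2,
      "systematic-review-other-medium-low": 2,
      "cohort": 2,
      "other": 1
    }
  },
  "cost_effectiveness": {
    "bands": [
      {"op": "lt", "value": 1.0, "code": 5},
      {"op": "le", "value": 2.0, "code": 4},
      {"op": "le", "value": 3.0, "code": 3}
    ],
    "else": 2,
    "unspecified": 1
  },
  "budget_impact": {
    "levels": {
      "significant savings": 5,
      "moderate savings": 4,
      "very slight change": 3,
      "no significant change": 2
    },
    "unspecified": 1
  },
  "financial_protection": {
    "bands": [
      {"op": "ge", "value": 100.0, "code": 5},
      {"op": "gt", "value": 75.0, "code": 4},
      {"op": "ge", "value": 50.0, "code": 3}
    ],
    "else": 2,
    "unspecified": 1
  }
}
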