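[
  {
    "name": "severe-triad",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "breathlessness",
        "category": "Good"
      },
      {
        "symptom": "fever_value",
        "category": "Average"
      },
      {
        "symptom": "sputum_production",
        "category": "Poor"
      }
    ],
    "consequent": "Severe"
  },
  {
    "name": "moderate-appetite-or-fever",
    "logic": "OR",
    "antecedents": [
      {
        "symptom": "appetite_loss",
        "category": "Average"
      },
      {
        "symptom": "fever_value",
        "category": "Good"
      }
    ],
    "consequent": "Moderate"
  },
  {
    "name": "breathlessness-average",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "breathlessness",
        "category": "Average"
      }
    ],
    "consequent": "Mild"
  },
  {
    "name": "breathlessness-good",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "breathlessness",
        "category": "Good"
      }
    ],
    "consequent": "Severe"
  },
  {
    "name": "sputum-average",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "sputum_production",
        "category": "Average"
      }
    ],
    "consequent": "Mild"
  },
  {
    "name": "sputum-good",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "sputum_production",
        "category": "Good"
      }
    ],
    "consequent": "Severe"
  },
  {
    "name": "fever-average",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "fever_value",
        "category": "Average"
      }
    ],
    "consequent": "Moderate"
  },
  {
    "name": "fever-good",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "fever_value",
        "category": "Good"
      }
    ],
    "consequent": "Severe",
    "weight": 20
  },
  {
    "name": "appetite-average",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "appetite_loss",
        "category": "Average"
      }
    ],
    "consequent": "Moderate"
  },
  {
    "name": "appetite-good",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "appetite_loss",
        "category": "Good"
      }
    ],
    "consequent": "Severe",
    "weight": 15
  },
  {
    "name": "hypoxia-average",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "oxygen_level",
        "category": "Average"
      }
    ],
    "consequent": "Moderate"
  },
  {
    "name": "hypoxia-good",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "oxygen_level",
        "category": "Good"
      }
    ],
    "consequent": "Severe"
  },
  {
    "name": "cough-average",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "cough_severity",
        "category": "Average"
      }
    ],
    "consequent": "Mild"
  },
  {
    "name": "cough-good",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "cough_severity",
        "category": "Good"
      }
    ],
    "consequent": "Severe"
  },
  {
    "name": "hemoptysis-or-confusion",
    "logic": "OR",
    "antecedents": [
      {
        "symptom": "hemoptysis",
        "category": "Good"
      },
      {
        "symptom": "confusion",
        "category": "Good"
      }
    ],
    "consequent": "Severe"
  },
  {
    "name": "fatigue-or-chest-pain",
    "logic": "OR",
    "antecedents": [
      {
        "symptom": "fatigue",
        "category": "Good"
      },
      {
        "symptom": "chest_pain",
        "category": "Good"
      }
    ],
    "consequent": "Moderate"
  },
  {
    "name": "prolonged-fever",
    "logic": "AND",
    "antecedents": [
      {
        "symptom": "fever_duration",
        "category": "Good"
      }
    ],
    "consequent": "Moderate"
  }
]
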