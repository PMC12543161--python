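{
  "breathlessness":    {"min": 0.0,  "max": 1.0,   "unit": "severity 0-1", "severity_inverted": false},
  "sputum_production": {"min": 0.0,  "max": 1.0,   "unit": "severity 0-1", "severity_inverted": false},
  "hemoptysis":        {"min": 0.0,  "max": 1.0,   "unit": "severity 0-1", "severity_inverted": false},
  "fatigue":           {"min": 0.0,  "max": 1.0,   "unit": "severity 0-1", "severity_inverted": false},
  "appetite_loss":     {"min": 0.0,  "max": 1.0,   "unit": "severity 0-1", "severity_inverted": false},
  "chest_pain":        {"min": 0.0,  "max": 1.0,   "unit": "severity 0-1", "severity_inverted": false},
  "cough_severity":    {"min": 0.0,  "max": 1.0,   "unit": "severity 0-1", "severity_inverted": false},
  "confusion":         {"min": 0.0,  "max": 1.0,   "unit": "severity 0-1", "severity_inverted": false},
  "fever_value":       {"min": 35.0, "max": 42.0,  "unit": "degC",         "severity_inverted": false},
  "oxygen_level":      {"min": 80.0, "max": 100.0, "unit": "% SpO2",       "severity_inverted": true},
  "fever_duration":    {"min": 0.0,  "max": 30.0,  "unit": "days",         "severity_inverted": false}
}
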