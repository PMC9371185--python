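{
  "_comment": "Default configuration for the three parallel fuzzy risk controllers. Membership breakpoints are reconstructions calibrated so that the documented stimulus exemplars (100/400/750 lx, 15/26/32 degC, 60/70/80 dB) land in their published linguistic terms and adjacent terms cross at membership 0.5; drop in alternative values here to re-parameterize without code changes.",
  "output": {
    "name": "risk",
    "universe": [0.0, 10.0],
    "order": ["Low Risk", "Medium Risk", "High Risk"],
    "terms": {
      "Low Risk": {"shape": "trapezoid", "params": [0.0, 0.0, 1.0, 5.0]},
      "Medium Risk": {"shape": "trapezoid", "params": [1.0, 5.0, 5.0, 9.0]},
      "High Risk": {"shape": "trapezoid", "params": [5.0, 9.0, 10.0, 10.0]}
    }
  },
  "duration": {
    "name": "duration",
    "unit": "s",
    "universe": [0.0, 600.0],
    "order": ["Short", "Medium", "Long"],
    "terms": {
      "Short": {"shape": "trapezoid", "params": [0.0, 0.0, 12.0, 22.0]},
      "Medium": {"shape": "trapezoid", "params": [12.0, 22.0, 30.0, 40.0]},
      "Long": {"shape": "trapezoid", "params": [30.0, 40.0, 600.0, 600.0]}
    }
  },
  "attention": {"name": "attention", "order": ["low", "normal"], "categorical": true},
  "stress": {"name": "stress", "order": ["low", "moderate", "high"], "categorical": true},
  "stimulus": {
    "brightness": {
      "name": "stimulus",
      "unit": "lx",
      "universe": [0.0, 2000.0],
      "order": ["Low", "Moderate", "High"],
      "terms": {
        "Low": {"shape": "trapezoid", "params": [0.0, 0.0, 150.0, 350.0]},
        "Moderate": {"shape": "trapezoid", "params": [150.0, 350.0, 500.0, 700.0]},
        "High": {"shape": "trapezoid", "params": [500.0, 700.0, 2000.0, 2000.0]}
      }
    },
    "temperature": {
      "name": "stimulus",
      "unit": "degC",
      "universe": [-10.0, 45.0],
      "order": ["Low", "Moderate", "High"],
      "terms": {
        "Low": {"shape": "trapezoid", "params": [-10.0, -10.0, 16.0, 22.0]},
        "Moderate": {"shape": "trapezoid", "params": [16.0, 22.0, 27.0, 33.0]},
        "High": {"shape": "trapezoid", "params": [28.0, 31.0, 45.0, 45.0]}
      }
    },
    "noise": {
      "name": "stimulus",
      "unit": "dB",
      "universe": [30.0, 90.0],
      "order": ["Low", "Moderate", "High"],
      "terms": {
        "Low": {"shape": "gaussian", "params": [40.0, 10.0]},
        "Moderate": {"shape": "gaussian", "params": [62.0, 9.0]},
        "High": {"shape": "gaussian", "params": [82.0, 9.0]}
      }
    }
  },
  "rules": [
    {"if": {"stimulus": "Moderate", "duration": "Short"}, "then": "Low Risk"},
    {"if": {"stimulus": "Moderate", "duration": "Medium"}, "then": "Low Risk"},
    {"if": {"stimulus": "Moderate", "duration": "Long"}, "then": "Low Risk"},
    {"if": {"stimulus": "Moderate", "stress": "high"}, "then": "Low Risk"},
    {"if": {"stimulus": "Moderate", "attention": "low"}, "then": "Low Risk"},
    {"if": {"stimulus": "Low", "duration": "Short"}, "then": "Low Risk"},
    {"if": {"stimulus": "Low", "duration": "Short", "stress": "high"}, "then": "Medium Risk"},
    {"if": {"stimulus": "Low", "duration": "Medium"}, "then": "Low Risk"},
    {"if": {"stimulus": "Low", "duration": "Medium", "stress": "moderate"}, "then": "Medium Risk"},
    {"if": {"stimulus": "Low", "duration": "Medium", "stress": "high"}, "then": "Medium Risk"},
    {"if": {"stimulus": "Low", "duration": "Medium", "attention": "low"}, "then": "Medium Risk"},
    {"if": {"stimulus": "Low", "duration": "Long"}, "then": "High Risk"},
    {"if": {"stimulus": "Low", "attention": "low", "stress": "high"}, "then": "High Risk"},
    {"if": {"stimulus": "High", "duration": "Short"}, "then": "Low Risk"},
    {"if": {"stimulus": "High", "duration": "Short", "stress": "high"}, "then": "Medium Risk"},
    {"if": {"stimulus": "High", "duration": "Medium"}, "then": "Low Risk"},
    {"if": {"stimulus": "High", "duration": "Medium", "stress": "moderate"}, "then": "Medium Risk"},
    {"if": {"stimulus": "High", "duration": "Medium", "stress": "high"}, "then": "Medium Risk"},
    {"if": {"stimulus": "High", "duration": "Medium", "attention": "low"}, "then": "Medium Risk"},
    {"if": {"stimulus": "High", "duration": "Long"}, "then": "High Risk"},
    {"if": {"stimulus": "High", "attention": "low", "stress": "high"}, "then": "High Risk"}
  ]
}
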