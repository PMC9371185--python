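{
  "_comment": "21-combination defuzzifier comparison suite on the temperature controller, one combination per rule regime; 'expected' is the risk category validated for each combination.",
  "modality": "temperature",
  "cases": [
    {"stimulus": 25, "duration": 10, "attention": "normal", "stress": "low", "expected": "Low"},
    {"stimulus": 25, "duration": 25, "attention": "normal", "stress": "moderate", "expected": "Low"},
    {"stimulus": 25, "duration": 50, "attention": "normal", "stress": "high", "expected": "Low"},
    {"stimulus": 25, "duration": 25, "attention": "low", "stress": "high", "expected": "Low"},
    {"stimulus": 25, "duration": 50, "attention": "low", "stress": "low", "expected": "Low"},
    {"stimulus": 15, "duration": 10, "attention": "normal", "stress": "low", "expected": "Low"},
    {"stimulus": 15, "duration": 10, "attention": "normal", "stress": "high", "expected": "Medium"},
    {"stimulus": 15, "duration": 25, "attention": "normal", "stress": "low", "expected": "Low"},
    {"stimulus": 15, "duration": 25, "attention": "normal", "stress": "moderate", "expected": "Medium"},
    {"stimulus": 15, "duration": 25, "attention": "normal", "stress": "high", "expected": "Medium"},
    {"stimulus": 15, "duration": 25, "attention": "low", "stress": "low", "expected": "Medium"},
    {"stimulus": 15, "duration": 50, "attention": "normal", "stress": "low", "expected": "High"},
    {"stimulus": 15, "duration": 10, "attention": "low", "stress": "high", "expected": "High"},
    {"stimulus": 32, "duration": 10, "attention": "normal", "stress": "low", "expected": "Low"},
    {"stimulus": 32, "duration": 10, "attention": "normal", "stress": "high", "expected": "Medium"},
    {"stimulus": 32, "duration": 25, "attention": "normal", "stress": "low", "expected": "Low"},
    {"stimulus": 32, "duration": 25, "attention": "normal", "stress": "moderate", "expected": "Medium"},
    {"stimulus": 32, "duration": 25, "attention": "normal", "stress": "high", "expected": "Medium"},
    {"stimulus": 32, "duration": 25, "attention": "low", "stress": "low", "expected": "Medium"},
    {"stimulus": 32, "duration": 50, "attention": "normal", "stress": "moderate", "expected": "High"},
    {"stimulus": 32, "duration": 10, "attention": "low", "stress": "high", "expected": "High"}
  ]
}
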