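{
  "_comment": "Worked-example regression suite: the nine published controller input combinations with their stimulus-level terms and risk categories.",
  "cases": [
    {"modality": "brightness", "stimulus": 100, "attention": "low", "stress": "high", "duration": 25, "level": "low", "category": "High"},
    {"modality": "brightness", "stimulus": 400, "attention": "normal", "stress": "low", "duration": 40, "level": "moderate", "category": "Low"},
    {"modality": "brightness", "stimulus": 750, "attention": "normal", "stress": "high", "duration": 10, "level": "high", "category": "Medium"},
    {"modality": "temperature", "stimulus": 15, "attention": "normal", "stress": "high", "duration": 10, "level": "low", "category": "Medium"},
    {"modality": "temperature", "stimulus": 26, "attention": "normal", "stress": "moderate", "duration": 25, "level": "moderate", "category": "Low"},
    {"modality": "temperature", "stimulus": 32, "attention": "low", "stress": "high", "duration": 40, "level": "high", "category": "High"},
    {"modality": "noise", "stimulus": 60, "attention": "low", "stress": "low", "duration": 25, "level": "moderate", "category": "Low"},
    {"modality": "noise", "stimulus": 70, "attention": "normal", "stress": "high", "duration": 10, "level": "moderate-high", "category": "Low"},
    {"modality": "noise", "stimulus": 80, "attention": "low", "stress": "moderate", "duration": 40, "level": "high", "category": "High"}
  ]
}
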