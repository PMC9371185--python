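{
  "_comment": "Synthetic 20-item sensory-profile instrument (5 items per Dunn quadrant, 1-5 Likert). Stand-in scoring map; the standardized questionnaire's item bank is proprietary and is not reproduced here.",
  "items": {
    "LR1": {"quadrant": "low_registration", "min": 1, "max": 5},
    "LR2": {"quadrant": "low_registration", "min": 1, "max": 5},
    "LR3": {"quadrant": "low_registration", "min": 1, "max": 5},
    "LR4": {"quadrant": "low_registration", "min": 1, "max": 5},
    "LR5": {"quadrant": "low_registration", "min": 1, "max": 5},
    "SK1": {"quadrant": "sensory_seeking", "min": 1, "max": 5},
    "SK2": {"quadrant": "sensory_seeking", "min": 1, "max": 5},
    "SK3": {"quadrant": "sensory_seeking", "min": 1, "max": 5},
    "SK4": {"quadrant": "sensory_seeking", "min": 1, "max": 5},
    "SK5": {"quadrant": "sensory_seeking", "min": 1, "max": 5},
    "SS1": {"quadrant": "sensory_sensitivity", "min": 1, "max": 5},
    "SS2": {"quadrant": "sensory_sensitivity", "min": 1, "max": 5},
    "SS3": {"quadrant": "sensory_sensitivity", "min": 1, "max": 5},
    "SS4": {"quadrant": "sensory_sensitivity", "min": 1, "max": 5},
    "SS5": {"quadrant": "sensory_sensitivity", "min": 1, "max": 5},
    "AV1": {"quadrant": "sensory_avoiding", "min": 1, "max": 5},
    "AV2": {"quadrant": "sensory_avoiding", "min": 1, "max": 5},
    "AV3": {"quadrant": "sensory_avoiding", "min": 1, "max": 5},
    "AV4": {"quadrant": "sensory_avoiding", "min": 1, "max": 5},
    "AV5": {"quadrant": "sensory_avoiding", "min": 1, "max": 5}
  }
}
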