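{
  "_comment": "Strategy knowledge base keyed (modality, stimulus level, risk category). The nine specific entries are the published exemplar strategies; '_default' templates cover the remaining combinations ({modality} and {level} are substituted).",
  "entries": {
    "brightness": {
      "low": {
        "High": "Brightness level is low. Enhance indoor brightness (e.g., draw the curtains open), use a phone to show pictures or videos that the child likes for comfort and attention."
      },
      "moderate": {
        "Low": "Brightness level is moderate. No impact."
      },
      "high": {
        "Medium": "Brightness level is high. Reduce indoor brightness (e.g., draw the curtains). Keep observing."
      }
    },
    "temperature": {
      "low": {
        "Medium": "Temperature level is low. Enhance temperature level (e.g., turn up the air-conditioner). Keep observing."
      },
      "moderate": {
        "Low": "Temperature level is moderate. Keep observing."
      },
      "high": {
        "High": "Temperature level is high. Reduce temperature level (e.g., turn on the fan). Provide some deep pressure (e.g., hugs or massage) input to child for comfort and attention."
      }
    },
    "noise": {
      "moderate": {
        "Low": "Noise level is moderate. Check other factors that may distract your child."
      },
      "moderate-high": {
        "Low": "Noise level is moderate-high. Keep observing."
      },
      "high": {
        "High": "Noise level is high. Try to reduce loud (e.g., use noise-cancelling headphones or play calming music). Provide a fidget toy with texture that child likes for comfort and attention."
      }
    }
  },
  "_default": {
    "Low": "{Modality} level is {level}. No impact.",
    "Medium": "{Modality} level is {level}. Adjust the {modality} level if possible. Keep observing.",
    "High": "{Modality} level is {level}. Adjust the {modality} level and comfort the child (e.g., deep pressure, a favorite fidget toy, or calming media)."
  }
}
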