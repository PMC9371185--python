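{
  "_comment": "Summary statistics from the original real-life evaluation cohort (30 ASD + 30 TD preschool children, three 30-min sessions each). These printed summaries are inputs to the evaluation arithmetic (effect sizes, SUS scores) and to the model-selection worked example; nothing here is computed by this package.",
  "ctrf": {
    "_comment": "Mean (SD) of caregiver/teacher C-TRF subscale ratings and caregiver-reported wrong prediction cases per session type.",
    "ASD": {
      "baseline": {
        "ctrf_attention_caregiver": [8.1, 3.5],
        "ctrf_attention_teacher": [8.6, 2.8],
        "ctrf_stress_caregiver": [4.3, 3.5],
        "ctrf_stress_teacher": [4.9, 4.0]
      },
      "monitoring": {
        "wrong_predictions_attention": [21.9, 15.7],
        "wrong_predictions_stress": [6.7, 5.0],
        "ctrf_attention_caregiver": [8.3, 3.2],
        "ctrf_attention_teacher": [8.7, 3.3],
        "ctrf_stress_caregiver": [4.4, 3.6],
        "ctrf_stress_teacher": [4.9, 3.9]
      },
      "intervention": {
        "wrong_predictions_attention": [11.0, 7.7],
        "wrong_predictions_stress": [4.2, 2.5],
        "ctrf_attention_caregiver": [6.5, 2.8],
        "ctrf_attention_teacher": [7.0, 2.9],
        "ctrf_stress_caregiver": [3.4, 3.3],
        "ctrf_stress_teacher": [3.7, 3.4]
      }
    },
    "TD": {
      "baseline": {
        "ctrf_attention_caregiver": [1.6, 1.6],
        "ctrf_attention_teacher": [2.0, 2.0],
        "ctrf_stress_caregiver": [1.6, 1.9],
        "ctrf_stress_teacher": [1.5, 1.9]
      },
      "monitoring": {
        "wrong_predictions_attention": [5.2, 4.2],
        "wrong_predictions_stress": [18.6, 8.4],
        "ctrf_attention_caregiver": [1.8, 1.8],
        "ctrf_attention_teacher": [2.2, 2.2],
        "ctrf_stress_caregiver": [1.7, 2.1],
        "ctrf_stress_teacher": [1.7, 1.9]
      },
      "intervention": {
        "wrong_predictions_attention": [4.8, 3.4],
        "wrong_predictions_stress": [13.3, 7.2],
        "ctrf_attention_caregiver": [1.5, 1.5],
        "ctrf_attention_teacher": [1.8, 2.0],
        "ctrf_stress_caregiver": [1.2, 1.8],
        "ctrf_stress_teacher": [1.3, 1.6]
      }
    }
  },
  "sus_item_means": {
    "ASD": [3.87, 1.67, 3.67, 3.73, 4.2, 1.07, 3.53, 1.13, 3.33, 2.8],
    "TD": [3.67, 2.07, 3.73, 3.93, 4.33, 1.07, 3.4, 1.2, 3.4, 2.93]
  },
  "model_comparison": {
    "_comment": "Published detector comparison on the 521-session recordings (not reproducible here; recordings unavailable). Accuracy in percent; inference time in ms per sample.",
    "attention": {
      "LR": {"accuracy": 65.71, "f1": 0.6949, "inference_time_ms": 0.0052},
      "KNN": {"accuracy": 81.9, "f1": 0.8319, "inference_time_ms": 0.0291},
      "RF": {"accuracy": 79.05, "f1": 0.8, "inference_time_ms": 0.0958},
      "ANN": {"accuracy": 80.95, "f1": 0.8246, "inference_time_ms": 0.004},
      "GBDT": {"accuracy": 86.67, "f1": 0.8772, "inference_time_ms": 0.0046}
    },
    "stress": {
      "LR": {"accuracy": 65.3, "f1": 0.5712, "inference_time_ms": 0.0013},
      "KNN": {"accuracy": 93.92, "f1": 0.9251, "inference_time_ms": 0.1041},
      "RF": {"accuracy": 98.82, "f1": 0.9851, "inference_time_ms": 0.0182},
      "ANN": {"accuracy": 96.89, "f1": 0.9592, "inference_time_ms": 0.0021},
      "GBDT": {"accuracy": 98.5, "f1": 0.9812, "inference_time_ms": 0.0366}
    }
  }
}
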