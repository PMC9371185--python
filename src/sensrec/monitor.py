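"""Real-time monitoring loop: sensors -> detectors -> controllers -> alerts.

For each second of a session: build the 14-feature vector, predict attention
and stress, update the per-modality atypical-response duration counters, run
the three fuzzy controllers in parallel, keep the maximum-risk assessment,
and emit an alert payload iff it is High Risk and a subscription is active.
Deterministic given the models and the stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .features import extract_features
from .fuzzy import FuzzyController, build_alert, build_all_controllers
from .fuzzy.engine import stimulus_level
from .types import Session, SensoryProfile

__all__ = ["MonitorEvent", "monitor"]

_CATEGORY_RANK = {"Low": 0, "Medium": 1, "High": 2}


@dataclass
class MonitorEvent:
    """One second of monitoring output."""

    timestamp: int
    attention: str
    stress: str
    assessments: dict  # modality -> RiskAssessment dict
    top_modality: str
    top_category: str
    alert: Optional[dict] = None

    def as_json(self) -> str:
        return json.dumps(
            {
                "t": self.timestamp,
                "attention": self.attention,
                "stress": self.stress,
                "assessments": self.assessments,
                "top_modality": self.top_modality,
                "top_category": self.top_category,
                "alert": self.alert,
            },
            sort_keys=True,
        )


def monitor(
    session: Session,
    profile: SensoryProfile,
    attention_model,
    stress_model,
    controllers: Optional[dict[str, FuzzyController]] = None,
    subscription: Optional[str] = None,
    log_path: Optional[str | Path] = None,
) -> tuple[list[MonitorEvent], list[dict]]:
    """Run the full per-second pipeline over ``session``.

    Returns (events, alerts); with ``log_path`` set, also writes the events
    as JSON lines.
    """
    controllers = controllers or build_all_controllers()
    durations = {m: 0 for m in controllers}
    events: list[MonitorEvent] = []
    alerts: list[dict] = []

    for record in session.records:
        fv = extract_features(record, profile, session.gender, session.age)
        x = np.asarray(fv.values, dtype=float).reshape(1, -1)
        attention = str(attention_model.predict(x)[0])
        stress = str(stress_model.predict(x)[0])

        stimulus_of = {
            "brightness": record.brightness,
            "temperature": record.temperature,
            "noise": record.noise,
        }
        assessments = {}
        top = None
        for modality, controller in controllers.items():
            value = stimulus_of[modality]
            # update this modality's atypical-response run length first
            level_degrees = controller.fuzzify_inputs(value, 0, attention, stress)["stimulus"]
            level = stimulus_level(level_degrees, controller.stimulus.order)
            atypical = (attention == "low" or stress == "high") and level != "moderate"
            durations[modality] = durations[modality] + 1 if atypical else 0

            assessment = controller.infer(value, durations[modality], attention, stress)
            assessments[modality] = assessment
            if top is None or _CATEGORY_RANK[assessment.category] > _CATEGORY_RANK[top.category]:
                top = assessment

        alert = build_alert(top, subscription, timestamp=record.timestamp)
        if alert is not None:
            alerts.append(alert)
        events.append(
            MonitorEvent(
                timestamp=record.timestamp,
                attention=attention,
                stress=stress,
                assessments={m: a.as_dict() for m, a in assessments.items()},
                top_modality=top.modality,
                top_category=top.category,
                alert=alert,
            )
        )

    if log_path is not None:
        Path(log_path).parent.mkdir(parents=True, exist_ok=True)
        with open(log_path, "w") as fh:
            for event in events:
                fh.write(event.as_json() + "\n")
    return events, alerts
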