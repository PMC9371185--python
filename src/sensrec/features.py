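"""Feature extraction for the attention/stress detectors.

Each 1 Hz sensor record is mapped to a 14-dimensional predictor vector:
five environmental channels, the four Dunn-quadrant profile scores, three
physiological summaries (GSR, heart rate, accelerometer mean absolute value
over the three axes), and two personal characteristics (gender, age).
"""

from __future__ import annotations

from typing import Optional

from .types import (
    FEATURE_NAMES,
    GENDER_ENCODING,
    FeatureVector,
    SensorRecord,
    Session,
    SensoryProfile,
    ValidationError,
)

__all__ = ["extract_features", "accel_mav", "impute_locf", "MissingChannelError"]


class MissingChannelError(ValueError):
    """A required sensor channel is missing and imputation is disabled."""


def accel_mav(ax: float, ay: float, az: float) -> float:
    """Mean absolute value of the three accelerometer axes: (|ax|+|ay|+|az|)/3."""
    return (abs(ax) + abs(ay) + abs(az)) / 3.0


def extract_features(
    record: SensorRecord,
    profile: SensoryProfile,
    gender: str,
    age: float,
) -> FeatureVector:
    """Build the canonical 14-feature vector from one record.

    All eight sensor channels must be present on ``record``; run
    :func:`impute_locf` on the session first if gap filling is wanted.
    """
    missing = record.missing_channels
    if missing:
        raise MissingChannelError(f"missing sensor channel(s): {', '.join(missing)}")
    if gender not in GENDER_ENCODING:
        raise ValidationError(f"gender must be one of {sorted(GENDER_ENCODING)}, got {gender!r}")
    values = {
        "temperature": record.temperature,
        "noise": record.noise,
        "humidity": record.humidity,
        "brightness": record.brightness,
        "air_pressure": record.air_pressure,
        **profile.as_dict(),
        "gsr": record.gsr,
        "heart_rate": record.heart_rate,
        "accel_mav": accel_mav(record.ax, record.ay, record.az),
        "gender": float(GENDER_ENCODING[gender]),
        "age": float(age),
    }
    return FeatureVector(tuple(float(values[name]) for name in FEATURE_NAMES))


def impute_locf(session: Session) -> Session:
    """Last-observation-carried-forward imputation of missing channels.

    Carries values forward within the session only; leading missing values
    (no prior observation) remain missing.  Off by default in every pipeline:
    call explicitly when wanted.
    """
    last: dict[str, Optional[float]] = {}
    out = []
    for record in session.records:
        updates = {}
        for name in record.__dataclass_fields__:
            if name == "timestamp":
                continue
            value = getattr(record, name)
            if value is None and last.get(name) is not None:
                updates[name] = last[name]
            elif value is not None:
                last[name] = value
        if updates:
            record = SensorRecord(
                timestamp=record.timestamp,
                **{
                    name: updates.get(name, getattr(record, name))
                    for name in record.__dataclass_fields__
                    if name != "timestamp"
                },
            )
        out.append(record)
    return session.with_records(out)
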