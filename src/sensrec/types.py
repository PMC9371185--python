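"""Core domain types for 1 Hz multi-sensor classroom sessions.

A recording session is an ordered run of :class:`SensorRecord` samples on a
0-based one-second grid, together with child metadata, an optional task
accuracy score and optional assessor labels.  Channels may be individually
missing on a record (``None``); they are never silently zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "CHANNELS",
    "FEATURE_NAMES",
    "GENDER_ENCODING",
    "SensorRecord",
    "Session",
    "SensoryProfile",
    "FeatureVector",
    "ValidationError",
]

#: Sensor channel names in canonical CSV column order (after the timestamp).
CHANNELS = (
    "temperature",
    "humidity",
    "noise",
    "brightness",
    "air_pressure",
    "gsr",
    "heart_rate",
    "ax",
    "ay",
    "az",
)

#: The 14 predictors used by the attention and stress detectors, fixed order:
#: 5 environmental, 4 sensory-profile quadrants, 3 physiological, 2 personal.
FEATURE_NAMES = (
    "temperature",
    "noise",
    "humidity",
    "brightness",
    "air_pressure",
    "low_registration",
    "sensory_seeking",
    "sensory_sensitivity",
    "sensory_avoiding",
    "gsr",
    "heart_rate",
    "accel_mav",
    "gender",
    "age",
)

#: Fixed encoding of the gender predictor.
GENDER_ENCODING = {"male": 0, "female": 1}


class ValidationError(ValueError):
    """Raised when a domain invariant is violated by input data."""


@dataclass(frozen=True)
class SensorRecord:
    """One 1 Hz multi-channel sample.

    ``timestamp`` is in whole seconds since session start.  Any sensor channel
    may be ``None`` (missing); :attr:`missing_channels` lists them.
    """

    timestamp: int
    temperature: Optional[float] = None  # °C
    humidity: Optional[float] = None  # %
    noise: Optional[float] = None  # dB
    brightness: Optional[float] = None  # lx
    air_pressure: Optional[float] = None  # kPa
    gsr: Optional[float] = None  # dimensionless sensor value, >= 0
    heart_rate: Optional[float] = None  # bpm
    ax: Optional[float] = None
    ay: Optional[float] = None
    az: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timestamp < 0 or self.timestamp != int(self.timestamp):
            raise ValidationError(f"timestamp must be a non-negative integer, got {self.timestamp!r}")
        if self.humidity is not None and not (0.0 <= self.humidity <= 100.0):
            raise ValidationError(f"humidity must be in [0, 100] %, got {self.humidity!r}")
        if self.heart_rate is not None and self.heart_rate <= 0:
            raise ValidationError(f"heart_rate must be > 0 bpm, got {self.heart_rate!r}")
        if self.gsr is not None and self.gsr < 0:
            raise ValidationError(f"gsr must be >= 0, got {self.gsr!r}")

    @property
    def missing_channels(self) -> tuple[str, ...]:
        return tuple(name for name in CHANNELS if getattr(self, name) is None)

    @property
    def accel(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        return (self.ax, self.ay, self.az)


@dataclass
class Session:
    """An ordered run of sensor records with child metadata.

    Records must be strictly increasing in timestamp; unit spacing is the
    nominal grid and any holes are reported by :attr:`gaps`.  ``task_accuracy``
    is the fraction of task items answered correctly (absent for sessions with
    no attention task, e.g. free relaxing).  Assessor labels are present only
    for sessions rated by a healthcare professional.
    """

    child_id: str
    gender: str  # {"male", "female"}
    age: float  # years
    records: list[SensorRecord] = field(default_factory=list)
    task_accuracy: Optional[float] = None
    assessor_attention_label: Optional[str] = None  # {"low", "normal"}
    assessor_stress_label: Optional[str] = None  # {"low", "moderate", "high"}
    start_time: Optional[str] = None  # wall-clock ISO timestamp, metadata only
    session_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gender not in GENDER_ENCODING:
            raise ValidationError(f"gender must be one of {sorted(GENDER_ENCODING)}, got {self.gender!r}")
        if self.task_accuracy is not None and not (0.0 <= self.task_accuracy <= 1.0):
            raise ValidationError(f"task_accuracy must be in [0, 1], got {self.task_accuracy!r}")
        if self.assessor_attention_label not in (None, "low", "normal"):
            raise ValidationError(f"invalid attention label {self.assessor_attention_label!r}")
        if self.assessor_stress_label not in (None, "low", "moderate", "high"):
            raise ValidationError(f"invalid stress label {self.assessor_stress_label!r}")
        ts = [r.timestamp for r in self.records]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("record timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Holes in the 1 Hz grid as ``(first_missing_t, n_missing)`` pairs."""
        out: list[tuple[int, int]] = []
        ts = [r.timestamp for r in self.records]
        for a, b in zip(ts, ts[1:]):
            if b - a > 1:
                out.append((a + 1, b - a - 1))
        return out

    def with_records(self, records: Sequence[SensorRecord]) -> "Session":
        return replace(self, records=list(records))


@dataclass(frozen=True)
class SensoryProfile:
    """Dunn-quadrant sensory-processing scores from the caregiver questionnaire.

    Each quadrant carries the raw sum of its item responses and a normalized
    score in [0, 1] (raw rescaled by the quadrant's attainable min/max sum).
    All four quadrants are always present.
    """

    low_registration: float
    sensory_seeking: float
    sensory_sensitivity: float
    sensory_avoiding: float
    raw: dict[str, int] = field(default_factory=dict, compare=False)

    QUADRANTS = ("low_registration", "sensory_seeking", "sensory_sensitivity", "sensory_avoiding")

    def __post_init__(self) -> None:
        for q in self.QUADRANTS:
            v = getattr(self, q)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"normalized {q} score must be in [0, 1], got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {q: getattr(self, q) for q in self.QUADRANTS}


@dataclass(frozen=True)
class FeatureVector:
    """The 14 predictors for attention/stress detection, in canonical order."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValidationError(f"expected {len(FEATURE_NAMES)} features, got {len(self.values)}")
        if self.accel_mav < 0:
            raise ValidationError("accel_mav must be >= 0")

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]

    @property
    def accel_mav(self) -> float:
        return self.values[FEATURE_NAMES.index("accel_mav")]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))
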