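"""Seeded classroom-session simulator.

Emulates the acquisition protocol the detectors were built for: a cohort of
children with ASD, each recorded over repeated ~15 min sessions at 1 Hz under
controlled environmental regimes (temperature, noise, brightness held at
moderate or extreme settings) while relaxing or performing attention tasks
scored 0-1.  Latent stress follows the protocol's scheme — relaxing in a
moderate environment is low stress, tasks in moderate/extreme environments
are moderate/high stress — and physiological channels (GSR, heart rate, hand
movement) respond additively to latent stress and low attention.

The simulator produces monotone, separable effects controlled entirely by
:class:`SimulationConfig`; it makes no claim of biophysical fidelity (see the
methods note).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .features import accel_mav
from .labeling import ATTENTION_THRESHOLD, assign_attention_label, assign_stress_label
from .profile import default_item_map, score_sensory_profile
from .types import FEATURE_NAMES, GENDER_ENCODING, Session, SensorRecord, SensoryProfile, ValidationError
from .session_io import write_session

__all__ = [
    "EnvironmentRegime",
    "SimulationConfig",
    "SimulatedSession",
    "simulate_environment",
    "simulate_child_session",
    "random_profile",
    "generate_dataset",
    "REGIME_CENTERS",
]

#: Per-modality stimulus centers (moderate anchored at the exemplar values the
#: fuzzy controllers label "moderate": 26 °C, 60 dB, 400 lx; extremes at the
#: exemplars labelled low/high: 15/32 °C, 40/80 dB, 100/750 lx).
REGIME_CENTERS = {
    "temperature": {"moderate": 26.0, "extreme-low": 15.0, "extreme-high": 32.0},
    "noise": {"moderate": 60.0, "extreme-low": 40.0, "extreme-high": 80.0},
    "brightness": {"moderate": 400.0, "extreme-low": 100.0, "extreme-high": 750.0},
}

_LEVELS = ("moderate", "extreme-low", "extreme-high")
STRESS_INDEX = {"low": 0, "moderate": 1, "high": 2}


@dataclass(frozen=True)
class EnvironmentRegime:
    """Controlled settings for the three manipulable modalities."""

    temperature: str = "moderate"
    noise: str = "moderate"
    brightness: str = "moderate"
    humidity_baseline: float = 50.0  # %
    pressure_baseline: float = 101.3  # kPa
    #: per-second jitter SDs, plus per-session baseline drift SDs for the
    #: weather channels ("*_session" keys): humidity and pressure barely move
    #: within a session but do vary day to day.
    amplitude: dict = field(
        default_factory=lambda: {
            "temperature": 0.3,
            "noise": 2.0,
            "brightness": 15.0,
            "humidity": 1.0,
            "air_pressure": 0.05,
            "humidity_session": 4.0,
            "air_pressure_session": 0.4,
        }
    )

    def __post_init__(self) -> None:
        for modality in ("temperature", "noise", "brightness"):
            if getattr(self, modality) not in _LEVELS:
                raise ValidationError(
                    f"unknown regime level {getattr(self, modality)!r} for {modality} (expected one of {_LEVELS})"
                )

    @property
    def overall(self) -> str:
        """'moderate' iff all three controlled modalities are moderate."""
        levels = (self.temperature, self.noise, self.brightness)
        return "moderate" if all(lv == "moderate" for lv in levels) else "extreme"


@dataclass
class SimulationConfig:
    """Cohort, session, effect-size and label-noise settings.

    Defaults mirror the acquisition protocol (35 children x 15 sessions of
    ~900 s at 1 Hz, with roughly 222/521 of sessions carrying assessor
    labels).  Physiology is baseline + additive per-level offsets; what
    matters downstream is monotone separability, which the gains control.
    """

    n_children: int = 35
    sessions_per_child: int = 15
    session_length: int = 900  # seconds at 1 Hz
    seed: int = 0
    labelled_fraction: float = 222 / 521
    label_noise: float = 0.05  # probability an assessor label is corrupted
    attention_threshold: float = ATTENTION_THRESHOLD
    prob_male: float = 29 / 35
    # physiological baselines (arbitrary but plausible sensor units)
    hr_baseline: float = 90.0  # bpm
    gsr_baseline: float = 200.0
    accel_baseline: float = 0.1  # mean absolute value
    # additive response per latent stress level (0=low, 1=moderate, 2=high)
    gsr_per_stress: float = 50.0
    hr_per_stress: float = 10.0
    accel_per_stress: float = 0.05
    # additive response when latent attention is low
    gsr_attention: float = 30.0
    hr_attention: float = 5.0
    accel_attention: float = 0.05
    # per-sample measurement noise (SD)
    gsr_sd: float = 10.0
    hr_sd: float = 3.0
    #: suppress day-to-day humidity/pressure drift (a controlled testing
    #: room rather than ordinary classrooms across days)
    controlled_weather: bool = False
    # probability of low latent attention by regime class
    p_low_attention_moderate: float = 0.15
    p_low_attention_extreme_base: float = 0.25
    p_low_attention_sensitivity_gain: float = 0.5

    def __post_init__(self) -> None:
        for name in ("labelled_fraction", "label_noise", "prob_male", "attention_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v!r}")
        if self.session_length < 60:
            raise ValidationError("session_length must be at least 60 s")
        if self.n_children < 1 or self.sessions_per_child < 1:
            raise ValidationError("cohort dimensions must be positive")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def strong_effects(cls, **overrides) -> "SimulationConfig":
        """Benchmark condition with large, channel-decoupled effect sizes.

        Stress drives the arousal channels (GSR, heart rate) strongly while
        low attention shows almost entirely in hand movement, and the
        regime/profile links to latent attention are strengthened so both
        classes are well represented.  Under this calibration the session
        means of the two targets are cleanly separable, which is what the
        detector sanity checks require of the generator.
        """
        params = dict(
            gsr_per_stress=100.0,
            hr_per_stress=20.0,
            accel_per_stress=0.05,
            gsr_attention=0.0,
            hr_attention=0.0,
            accel_attention=0.5,
            p_low_attention_moderate=0.3,
            p_low_attention_extreme_base=0.5,
            p_low_attention_sensitivity_gain=0.5,
            label_noise=0.0,
            controlled_weather=True,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class SimulatedSession:
    """A generated session plus the latent states that produced it."""

    session: Session
    profile: SensoryProfile
    regime: EnvironmentRegime
    activity: str  # {"relaxing", "task"}
    latent_attention: str  # {"low", "normal"}
    latent_stress: str  # {"low", "moderate", "high"}


def simulate_environment(
    regime: EnvironmentRegime, length: int, seed: Optional[int | np.random.Generator] = None
) -> dict[str, np.ndarray]:
    """Environmental channel streams for ``length`` seconds under ``regime``.

    Each stream is its regime center plus Gaussian jitter of the configured
    amplitude; reproducible under a fixed seed.
    """
    if length < 1:
        raise ValidationError("length must be >= 1 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for modality in ("temperature", "noise", "brightness"):
        center = REGIME_CENTERS[modality][getattr(regime, modality)]
        out[modality] = center + regime.amplitude[modality] * rng.standard_normal(length)
    humidity_base = regime.humidity_baseline + regime.amplitude.get("humidity_session", 0.0) * rng.standard_normal()
    pressure_base = regime.pressure_baseline + regime.amplitude.get("air_pressure_session", 0.0) * rng.standard_normal()
    out["humidity"] = np.clip(
        humidity_base + regime.amplitude["humidity"] * rng.standard_normal(length), 0.0, 100.0
    )
    out["air_pressure"] = pressure_base + regime.amplitude["air_pressure"] * rng.standard_normal(length)
    out["brightness"] = np.clip(out["brightness"], 0.0, None)
    return out


def random_profile(rng: np.random.Generator) -> SensoryProfile:
    """A random child profile drawn on the bundled synthetic instrument."""
    item_map = default_item_map()
    responses = {
        item: int(rng.integers(spec["min"], spec["max"] + 1)) for item, spec in item_map.items()
    }
    return score_sensory_profile(responses, item_map)


def simulate_child_session(
    profile: SensoryProfile,
    regime: EnvironmentRegime,
    activity: str,
    config: SimulationConfig,
    seed: Optional[int | np.random.Generator] = None,
    child_id: str = "sim-child",
    gender: str = "male",
    age: float = 5.0,
) -> SimulatedSession:
    """Simulate one recording session.

    Latent stress follows the acquisition scheme for (activity, regime);
    task accuracy (task sessions only) is Beta-distributed on the side of the
    attention threshold chosen by the latent attention state, so that the
    information-gain split is recoverable from the scores; GSR, heart rate
    and movement respond additively to latent stress and low attention.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent_stress = assign_stress_label(activity, regime.overall)
    s_idx = STRESS_INDEX[latent_stress]

    if activity == "task":
        if regime.overall == "extreme":
            p_low = min(
                config.p_low_attention_extreme_base
                + config.p_low_attention_sensitivity_gain * profile.sensory_sensitivity,
                0.95,
            )
        else:
            p_low = config.p_low_attention_moderate
        low_attention = rng.random() < p_low
        thr = config.attention_threshold
        beta = rng.beta(2.0, 2.0)
        task_accuracy = thr * beta if low_attention else thr + (1.0 - thr) * beta
        # keep strictly on the intended side of the threshold
        task_accuracy = float(min(max(task_accuracy, 0.0), 1.0))
        if not low_attention and task_accuracy <= thr:
            task_accuracy = min(thr + 1e-6, 1.0)
        latent_attention = assign_attention_label(task_accuracy, thr)
    else:
        task_accuracy = None
        latent_attention = "normal"

    n = config.session_length
    env = simulate_environment(regime, n, rng)
    attn_low = 1.0 if latent_attention == "low" else 0.0
    gsr_mean = config.gsr_baseline + config.gsr_per_stress * s_idx + config.gsr_attention * attn_low
    hr_mean = config.hr_baseline + config.hr_per_stress * s_idx + config.hr_attention * attn_low
    mav_mean = config.accel_baseline + config.accel_per_stress * s_idx + config.accel_attention * attn_low
    gsr = np.clip(gsr_mean + config.gsr_sd * rng.standard_normal(n), 0.0, None)
    hr = np.clip(hr_mean + config.hr_sd * rng.standard_normal(n), 30.0, None)
    # axis draws scaled so E[(|ax|+|ay|+|az|)/3] equals the target MAV
    axis_sigma = mav_mean * np.sqrt(np.pi / 2.0)
    axes = axis_sigma * rng.standard_normal((n, 3))

    records = [
        SensorRecord(
            timestamp=t,
            temperature=float(env["temperature"][t]),
            humidity=float(env["humidity"][t]),
            noise=float(env["noise"][t]),
            brightness=float(env["brightness"][t]),
            air_pressure=float(env["air_pressure"][t]),
            gsr=float(gsr[t]),
            heart_rate=float(hr[t]),
            ax=float(axes[t, 0]),
            ay=float(axes[t, 1]),
            az=float(axes[t, 2]),
        )
        for t in range(n)
    ]
    session = Session(
        child_id=child_id,
        gender=gender,
        age=age,
        records=records,
        task_accuracy=task_accuracy,
    )
    return SimulatedSession(session, profile, regime, activity, latent_attention, latent_stress)


def _make_regime(config: SimulationConfig, **levels) -> EnvironmentRegime:
    regime = EnvironmentRegime(**levels)
    if config.controlled_weather:
        amp = dict(regime.amplitude)
        amp["humidity_session"] = 0.0
        amp["air_pressure_session"] = 0.0
        regime = EnvironmentRegime(**levels, amplitude=amp)
    return regime


def _session_conditions(
    rng: np.random.Generator, index: int, config: SimulationConfig
) -> tuple[str, EnvironmentRegime]:
    """Cycle sessions through the three protocol conditions; extreme sessions
    perturb one randomly chosen modality in a random direction."""
    kind = index % 3
    if kind == 0:
        return "relaxing", _make_regime(config)
    if kind == 1:
        return "task", _make_regime(config)
    modality = ("temperature", "noise", "brightness")[int(rng.integers(3))]
    direction = "extreme-high" if rng.random() < 0.5 else "extreme-low"
    if modality == "noise" and direction == "extreme-low":
        direction = "extreme-high"  # a quiet room is not a stressor
    return "task", _make_regime(config, **{modality: direction})


def _corrupt(label: str, choices: tuple[str, ...], rng: np.random.Generator) -> str:
    others = [c for c in choices if c != label]
    return others[int(rng.integers(len(others)))]


def generate_dataset(
    config: SimulationConfig, out_dir: Optional[str | Path] = None
) -> tuple[pd.DataFrame, list[SimulatedSession]]:
    """Generate the full cohort.

    Returns a per-session labelled feature table (one row per session: the 14
    predictors averaged over the session, context columns, latent and — for a
    configurable fraction — assessor labels) plus the simulated sessions.
    With ``out_dir`` set, also writes each session in the CSV dialect and a
    ``manifest.json`` recording seed and config; generation is byte-identical
    across runs with the same config.
    """
    rows = []
    sims: list[SimulatedSession] = []
    for c in range(config.n_children):
        child_rng = np.random.default_rng(np.random.SeedSequence((config.seed, c)))
        gender = "male" if child_rng.random() < config.prob_male else "female"
        age = float(np.round(child_rng.uniform(3.0, 7.6), 1))
        profile = random_profile(child_rng)
        child_id = f"child-{c:03d}"
        for s in range(config.sessions_per_child):
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, c, s)))
            activity, regime = _session_conditions(rng, s, config)
            sim = simulate_child_session(
                profile, regime, activity, config, rng, child_id=child_id, gender=gender, age=age
            )
            sim.session.session_id = f"{child_id}-s{s:02d}"

            labelled = rng.random() < config.labelled_fraction
            if labelled:
                attn = sim.latent_attention
                stress = sim.latent_stress
                if rng.random() < config.label_noise:
                    attn = _corrupt(attn, ("low", "normal"), rng)
                if rng.random() < config.label_noise:
                    stress = _corrupt(stress, ("low", "moderate", "high"), rng)
                sim.session.assessor_attention_label = attn
                sim.session.assessor_stress_label = stress
            sims.append(sim)

            frame = pd.DataFrame(
                {
                    "temperature": [r.temperature for r in sim.session.records],
                    "noise": [r.noise for r in sim.session.records],
                    "humidity": [r.humidity for r in sim.session.records],
                    "brightness": [r.brightness for r in sim.session.records],
                    "air_pressure": [r.air_pressure for r in sim.session.records],
                    "gsr": [r.gsr for r in sim.session.records],
                    "heart_rate": [r.heart_rate for r in sim.session.records],
                    "accel_mav": [accel_mav(r.ax, r.ay, r.az) for r in sim.session.records],
                }
            )
            means = frame.mean()
            row = {name: means[name] for name in means.index}
            row.update(profile.as_dict())
            row.update(
                {
                    "gender": float(GENDER_ENCODING[gender]),
                    "age": age,
                    "child_id": child_id,
                    "session_id": sim.session.session_id,
                    "activity": activity,
                    "regime_class": regime.overall,
                    "task_accuracy": sim.session.task_accuracy,
                    "attention_label": sim.latent_attention,
                    "stress_label": sim.latent_stress,
                    "assessor_attention_label": sim.session.assessor_attention_label,
                    "assessor_stress_label": sim.session.assessor_stress_label,
                    "source": "simulated",
                }
            )
            rows.append(row)

    dataset = pd.DataFrame(rows)[
        list(FEATURE_NAMES)
        + [
            "child_id",
            "session_id",
            "activity",
            "regime_class",
            "task_accuracy",
            "attention_label",
            "stress_label",
            "assessor_attention_label",
            "assessor_stress_label",
            "source",
        ]
    ]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sim in sims:
            write_session(sim.session, out_dir / f"{sim.session.session_id}.csv")
        dataset.to_csv(out_dir / "dataset.csv", index=False)
        manifest = {"seed": config.seed, "config": config.as_dict(), "n_sessions": len(sims)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return dataset, sims
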