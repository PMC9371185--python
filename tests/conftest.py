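import numpy as np
import pytest

from sensrec import (
    Session,
    SensorRecord,
    SensoryProfile,
    SimulationConfig,
    generate_dataset,
)


def make_record(t: int, **overrides) -> SensorRecord:
    base = dict(
        temperature=26.0,
        humidity=50.0,
        noise=60.0,
        brightness=400.0,
        air_pressure=101.3,
        gsr=200.0,
        heart_rate=90.0,
        ax=0.1,
        ay=-0.05,
        az=0.02,
    )
    base.update(overrides)
    return SensorRecord(timestamp=t, **base)


@pytest.fixture
def small_session() -> Session:
    return Session(
        child_id="c-01",
        gender="male",
        age=5.2,
        records=[make_record(t) for t in range(30)],
        task_accuracy=0.75,
        assessor_attention_label="normal",
        assessor_stress_label="low",
        session_id="c-01-s00",
    )


@pytest.fixture
def mid_profile() -> SensoryProfile:
    return SensoryProfile(
        low_registration=0.5,
        sensory_seeking=0.5,
        sensory_sensitivity=0.5,
        sensory_avoiding=0.5,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small fully-labelled noise-free cohort shared across tests."""
    config = SimulationConfig(
        n_children=6,
        sessions_per_child=6,
        session_length=60,
        seed=11,
        labelled_fraction=1.0,
        label_noise=0.0,
    )
    dataset, sims = generate_dataset(config)
    return config, dataset, sims


@pytest.fixture(scope="session")
def strong_dataset():
    """The strong-effects benchmark cohort (400 labelled sessions)."""
    config = SimulationConfig.strong_effects(
        n_children=40, sessions_per_child=10, session_length=60, seed=7, labelled_fraction=1.0
    )
    dataset, _ = generate_dataset(config)
    return config, dataset
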