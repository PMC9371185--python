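"""Default controller configuration, strategy catalog and test suites.

All numeric membership parameters and the 21-rule base live in
``sensrec/data/controllers.json`` so that alternative calibrations can be
dropped in without touching code.  The shipped breakpoints are calibrated so
that each documented stimulus exemplar (100/400/750 lx, 15/26/32 °C,
60/70/80 dB) fuzzifies to its published linguistic level and adjacent terms
cross at membership 0.5.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

from .engine import FuzzyController, FuzzyRule, LinguisticVariable
from .membership import Trapezoid

__all__ = [
    "load_controller_config",
    "load_strategy_catalog",
    "build_controller",
    "build_all_controllers",
    "load_defuzz_suite",
    "load_worked_examples",
    "two_rule_demo_controller",
    "MODALITIES",
]

MODALITIES = ("brightness", "temperature", "noise")


def _read_data(name: str) -> dict:
    return json.loads(resources.files("sensrec.data").joinpath(name).read_text())


def load_controller_config(path: Optional[str | Path] = None) -> dict:
    return json.loads(Path(path).read_text()) if path else _read_data("controllers.json")


def load_strategy_catalog(path: Optional[str | Path] = None) -> dict:
    return json.loads(Path(path).read_text()) if path else _read_data("strategy_catalog.json")


def _rules_from_config(config: dict) -> list[FuzzyRule]:
    return [FuzzyRule(dict(r["if"]), r["then"]) for r in config["rules"]]


def build_controller(
    modality: str,
    config: Optional[dict] = None,
    strategy_catalog: Optional[dict] = None,
) -> FuzzyController:
    """Instantiate one modality's controller from (default) JSON config."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r} (expected one of {MODALITIES})")
    config = config or load_controller_config()
    catalog = strategy_catalog or load_strategy_catalog()
    return FuzzyController(
        modality=modality,
        stimulus=LinguisticVariable.from_config(config["stimulus"][modality]),
        duration=LinguisticVariable.from_config(config["duration"]),
        attention=LinguisticVariable.from_config(config["attention"]),
        stress=LinguisticVariable.from_config(config["stress"]),
        output=LinguisticVariable.from_config(config["output"]),
        rules=_rules_from_config(config),
        strategy_catalog=catalog,
    )


def build_all_controllers(
    config: Optional[dict] = None, strategy_catalog: Optional[dict] = None
) -> dict[str, FuzzyController]:
    config = config or load_controller_config()
    catalog = strategy_catalog or load_strategy_catalog()
    return {m: build_controller(m, config, catalog) for m in MODALITIES}


def load_defuzz_suite() -> tuple[str, list[dict]]:
    """The shipped 21-combination defuzzifier comparison suite."""
    obj = _read_data("defuzz_suite.json")
    return obj["modality"], obj["cases"]


def load_worked_examples() -> list[dict]:
    """The nine published worked-example input combinations."""
    return _read_data("table5_suite.json")["cases"]


def two_rule_demo_controller() -> FuzzyController:
    """The classic two-rule illustration of why LOM beats the centroid here.

    Rules: "IF temperature is High AND duration is Short THEN Low Risk" and
    "IF temperature is High AND duration is Long THEN High Risk".  The demo
    widens Short and Long so they overlap (the production terms are disjoint
    by design); with a high temperature and a duration approaching Long, both
    rules fire, the centroid averages the two consequents into Medium Risk,
    and LOM correctly reports High Risk.
    """
    config = load_controller_config()
    duration = LinguisticVariable(
        "duration",
        {"Short": Trapezoid(0, 0, 12, 30), "Long": Trapezoid(20, 35, 600, 600)},
        ("Short", "Long"),
        (0.0, 600.0),
        "s",
    )
    rules = [
        FuzzyRule({"stimulus": "High", "duration": "Short"}, "Low Risk"),
        FuzzyRule({"stimulus": "High", "duration": "Long"}, "High Risk"),
    ]
    return FuzzyController(
        modality="temperature",
        stimulus=LinguisticVariable.from_config(config["stimulus"]["temperature"]),
        duration=duration,
        attention=LinguisticVariable.from_config(config["attention"]),
        stress=LinguisticVariable.from_config(config["stress"]),
        output=LinguisticVariable.from_config(config["output"]),
        rules=rules,
        strategy_catalog=load_strategy_catalog(),
        expected_rule_count=2,
        check_coverage=False,
    )
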