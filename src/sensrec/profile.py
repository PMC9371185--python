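"""Sensory-profile questionnaire scoring.

The caregiver questionnaire classifies a child's sensory-processing pattern
under Dunn's four quadrants (low registration, sensory seeking, sensory
sensitivity, sensory avoiding).  Because the standardized item bank is
proprietary, scoring is driven by a configurable item-to-quadrant map; a
synthetic 20-item instrument (5 items per quadrant, 1-5 Likert) is bundled
and used throughout the tests.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

from .types import SensoryProfile, ValidationError

__all__ = ["load_item_map", "default_item_map", "score_sensory_profile", "ConfigurationError"]


class ConfigurationError(KeyError):
    """An item id is absent from the configured item-to-quadrant map."""


def load_item_map(path: str | Path) -> dict[str, dict]:
    """Load an item map JSON ``{item_id: {quadrant, min, max}}``."""
    obj = json.loads(Path(path).read_text())
    return _validate_map(obj["items"] if "items" in obj else obj)


def default_item_map() -> dict[str, dict]:
    """The bundled synthetic 20-item instrument."""
    text = resources.files("sensrec.data").joinpath("profile_items.json").read_text()
    return _validate_map(json.loads(text)["items"])


def _validate_map(items: Mapping[str, Mapping]) -> dict[str, dict]:
    out = {}
    for item_id, spec in items.items():
        if item_id.startswith("_"):
            continue
        quadrant = spec["quadrant"]
        if quadrant not in SensoryProfile.QUADRANTS:
            raise ConfigurationError(f"item {item_id!r}: unknown quadrant {quadrant!r}")
        lo, hi = int(spec["min"]), int(spec["max"])
        if lo >= hi:
            raise ConfigurationError(f"item {item_id!r}: empty Likert range [{lo}, {hi}]")
        out[item_id] = {"quadrant": quadrant, "min": lo, "max": hi}
    if not out:
        raise ConfigurationError("item map is empty")
    return out


def score_sensory_profile(
    responses: Mapping[str, int],
    item_map: Optional[Mapping[str, Mapping]] = None,
) -> SensoryProfile:
    """Score questionnaire ``responses`` into a :class:`SensoryProfile`.

    Each quadrant's raw score is the sum of its item responses; the
    normalized score rescales the raw sum by the quadrant's attainable
    minimum and maximum so that it lies in [0, 1].  Raising any single item
    response can only raise (never lower) its quadrant's score.
    """
    item_map = dict(item_map) if item_map is not None else default_item_map()
    for item_id in responses:
        if item_id not in item_map:
            raise ConfigurationError(f"unknown item id {item_id!r}")
    raw = {q: 0 for q in SensoryProfile.QUADRANTS}
    bounds = {q: [0, 0] for q in SensoryProfile.QUADRANTS}
    for item_id, spec in item_map.items():
        q = spec["quadrant"]
        bounds[q][0] += spec["min"]
        bounds[q][1] += spec["max"]
        if item_id not in responses:
            raise ValidationError(f"missing response for item {item_id!r}")
        value = responses[item_id]
        if not (spec["min"] <= value <= spec["max"]):
            raise ValidationError(
                f"response {value!r} for item {item_id!r} outside Likert range [{spec['min']}, {spec['max']}]"
            )
        raw[q] += int(value)

    normalized = {}
    for q in SensoryProfile.QUADRANTS:
        lo, hi = bounds[q]
        if hi == lo:  # quadrant has no items in this map
            raise ConfigurationError(f"item map defines no items for quadrant {q!r}")
        normalized[q] = (raw[q] - lo) / (hi - lo)
    return SensoryProfile(raw=raw, **normalized)
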