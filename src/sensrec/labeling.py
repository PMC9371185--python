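"""Label assignment and entropy-based split selection.

Assessor labels cover only part of the recorded sessions, so the remaining
sessions are labelled by rules: a threshold on task accuracy for attention
(placed where the information gain of the assessor-labelled sample is
maximal) and a deterministic (activity, environment-regime) mapping for
stress.  Entropy is Shannon entropy in bits; the argmax split is
base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import ValidationError

__all__ = [
    "entropy",
    "information_gain",
    "best_split",
    "assign_attention_label",
    "assign_stress_label",
    "SplitResult",
    "ATTENTION_THRESHOLD",
    "STRESS_RULES",
]

#: Default task-accuracy cut: accuracy strictly above it is normal attention.
ATTENTION_THRESHOLD = 0.6

#: (activity, overall regime class) -> stress label.  The (relaxing, extreme)
#: cell is deliberately undefined: the acquisition protocol never produced it.
STRESS_RULES = {
    ("relaxing", "moderate"): "low",
    ("task", "moderate"): "moderate",
    ("task", "extreme"): "high",
}


@dataclass
class SplitResult:
    """Best threshold split of scores against labels, with its candidate table."""

    threshold: float
    information_gain: float  # bits
    parent_entropy: float  # bits
    candidates: list[tuple[float, float]] = field(default_factory=list)  # (threshold, gain)
    degenerate: bool = False  # all labels identical

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "information_gain": self.information_gain,
            "parent_entropy": self.parent_entropy,
            "degenerate": self.degenerate,
            "candidates": [list(c) for c in self.candidates],
        }


def entropy(labels: Sequence) -> float:
    """Shannon entropy of a label sequence in bits: H = -sum p_i log2 p_i."""
    labels = list(labels)
    if not labels:
        raise ValidationError("entropy of an empty label sequence is undefined")
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(scores: Sequence[float], labels: Sequence, threshold: float) -> float:
    """Entropy reduction from splitting at ``threshold`` (sides <= t and > t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(list(labels), dtype=object)
    if scores.shape[0] != labels.shape[0]:
        raise ValidationError("scores and labels must be aligned")
    if scores.shape[0] == 0:
        raise ValidationError("cannot compute information gain on empty data")
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    left = scores <= threshold
    n = scores.shape[0]
    h = entropy(labels)
    child = 0.0
    for mask in (left, ~left):
        if mask.any():
            child += (mask.sum() / n) * entropy(labels[mask])
    gain = h - child
    return float(max(gain, 0.0))  # clip tiny negative float error


def best_split(scores: Sequence[float], labels: Sequence) -> SplitResult:
    """Exhaustive information-gain maximization over midpoint thresholds.

    Candidate thresholds sit at midpoints between consecutive distinct sorted
    scores; ties in gain break toward the smaller threshold.  If all labels
    are identical the result is flagged degenerate with zero gain.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if len(set(scores.tolist())) < 2:
        raise ValidationError("best_split requires at least 2 distinct scores")
    parent = entropy(labels)
    distinct = np.unique(scores)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    table = [(float(t), information_gain(scores, labels, t)) for t in candidates]
    if len(set(labels)) == 1:
        return SplitResult(float(candidates[0]), 0.0, parent, table, degenerate=True)
    best_t, best_gain = max(table, key=lambda c: (c[1], -c[0]))
    return SplitResult(best_t, best_gain, parent, table)


def assign_attention_label(task_accuracy: float, threshold: float = ATTENTION_THRESHOLD) -> str:
    """``normal`` iff task accuracy is strictly above the threshold, else ``low``."""
    if not (0.0 <= task_accuracy <= 1.0):
        raise ValidationError(f"task_accuracy must be in [0, 1], got {task_accuracy!r}")
    return "normal" if task_accuracy > threshold else "low"


def assign_stress_label(activity: str, regime_class: str) -> str:
    """Stress from session context: relaxing+moderate -> low; task+moderate ->
    moderate; task+extreme -> high.  (relaxing, extreme) is refused."""
    if activity not in ("relaxing", "task"):
        raise ValidationError(f"activity must be 'relaxing' or 'task', got {activity!r}")
    if regime_class not in ("moderate", "extreme"):
        raise ValidationError(f"regime class must be 'moderate' or 'extreme', got {regime_class!r}")
    key = (activity, regime_class)
    if key not in STRESS_RULES:
        raise ValidationError(f"stress level for {key} is undefined by the labelling scheme")
    return STRESS_RULES[key]
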