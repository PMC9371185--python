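"""Evaluation-study arithmetic.

Scoring for the two standardized instruments used to rate the system —
an adapted Caregiver-Teacher Report Form (C-TRF; 0/1/2 items summed per
subscale) and the 10-item System Usability Scale (SUS; 0-100 after the
odd/even normalization) — plus the comparison statistics: paired t-tests,
pooled-SD Cohen's d with the conventional magnitude bands, and per-session
aggregation of caregiver-reported wrong-prediction cases.

Cohen's d here is the mean change between two sessions divided by the
pooled SD sqrt((s1^2 + s2^2) / 2) of the two sessions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

__all__ = [
    "CtrfResponse",
    "EffectSizeResult",
    "score_ctrf",
    "score_sus",
    "cohens_d",
    "effect_magnitude",
    "paired_t",
    "summarize_sessions",
    "load_reference_cohort",
    "SESSION_TYPES",
]

SESSION_TYPES = ("baseline", "monitoring", "intervention")

#: Synthetic 10+10-item adapted C-TRF layout used by the tests; the real
#: adapted item list is configurable (it is not public).
DEFAULT_CTRF_ITEMS = {
    "attention": tuple(f"AP{i}" for i in range(1, 11)),
    "stress": tuple(f"AD{i}" for i in range(1, 11)),
}


@dataclass(frozen=True)
class CtrfResponse:
    """One rater's adapted C-TRF form: per-item scores in {0, 1, 2}."""

    rater: str  # {"caregiver", "teacher"}
    items: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.rater not in ("caregiver", "teacher"):
            raise ValidationError(f"rater must be 'caregiver' or 'teacher', got {self.rater!r}")
        for item, score in self.items.items():
            if score not in (0, 1, 2):
                raise ValidationError(f"C-TRF item {item!r} must score 0, 1 or 2, got {score!r}")


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    magnitude: str  # {"negligible", "small", "moderate", "large"}


def score_ctrf(
    response: CtrfResponse, item_map: Optional[Mapping[str, Sequence[str]]] = None
) -> dict[str, int]:
    """Subscale scores (sum of items; higher = more problems) for the
    Attention Problem and Anxious/Depressed ("stress") subscales."""
    item_map = item_map or DEFAULT_CTRF_ITEMS
    out = {}
    for subscale, items in item_map.items():
        total = 0
        for item in items:
            if item not in response.items:
                raise ValidationError(f"missing C-TRF item {item!r}")
            total += int(response.items[item])
        out[f"{subscale}_score"] = total
    return out


def score_sus(item_scores: Sequence[float]) -> float:
    """Overall SUS score on 0-100.

    Each of the 10 items is rated 1-5; odd-position (positively worded)
    items contribute (score - 1), even-position (negatively worded) items
    contribute (5 - score); the contribution sum is multiplied by 2.5.
    Item means across respondents are accepted, so scores may be fractional;
    by linearity the SUS of the item means equals the mean per-respondent
    SUS.
    """
    scores = [float(s) for s in item_scores]
    if len(scores) != 10:
        raise ValidationError(f"SUS requires exactly 10 item scores, got {len(scores)}")
    if any(not (1.0 <= s <= 5.0) for s in scores):
        raise ValidationError("SUS item scores must lie in [1, 5]")
    contributions = [(s - 1.0) if i % 2 == 0 else (5.0 - s) for i, s in enumerate(scores)]
    return 2.5 * sum(contributions)


def effect_magnitude(d: float) -> str:
    """Conventional bands: small 0.2 <= |d| < 0.5, moderate 0.5 <= |d| < 0.8,
    large |d| >= 0.8; below 0.2 is negligible."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "moderate"
    if a >= 0.2:
        return "small"
    return "negligible"


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> EffectSizeResult:
    """Cohen's d from two sessions' summary statistics:
    d = (mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2) / 2)."""
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("standard deviations must be non-negative")
    pooled = math.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if pooled == 0.0:
        raise ValidationError("effect size undefined: both standard deviations are zero")
    d = (mean_a - mean_b) / pooled
    return EffectSizeResult(d=d, magnitude=effect_magnitude(d))


def paired_t(differences: Sequence[float]) -> dict[str, float]:
    """Two-tailed paired t-test on per-participant differences:
    t = mean(diff) / (sd(diff) / sqrt(n)), p from Student t with n-1 df."""
    diff = np.asarray(differences, dtype=float)
    n = diff.shape[0]
    if n < 2:
        raise ValidationError("paired t-test needs at least 2 differences")
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff.mean() == 0.0:
            return {"t": 0.0, "p_two_tailed": 1.0, "n": n}
        raise ValidationError("degenerate paired t-test: zero variance, nonzero mean")
    t = diff.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return {"t": float(t), "p_two_tailed": float(p), "n": n}


def summarize_sessions(
    corrections: pd.DataFrame,
    ctrf_scores: pd.DataFrame,
    group: str,
) -> pd.DataFrame:
    """Mean (SD) per session type of the six rating parameters.

    ``corrections`` columns: participant_id, session_type, attention, stress
    (wrong-prediction counts); ``ctrf_scores`` columns: participant_id,
    session_type, rater, attention_score, stress_score.  Returns one row per
    session type with mean/SD columns; single-participant groups get SD 0
    and a small-n flag.
    """
    if group not in ("ASD", "TD"):
        raise ValidationError(f"group must be 'ASD' or 'TD', got {group!r}")
    if ctrf_scores.empty:
        raise ValidationError(f"no participants in group {group!r}")

    rows = []
    for session_type in SESSION_TYPES:
        row: dict = {"group": group, "session_type": session_type}
        c = corrections[corrections["session_type"] == session_type]
        for target in ("attention", "stress"):
            values = c[target].astype(float)
            row[f"wrong_predictions_{target}_mean"] = values.mean() if len(values) else float("nan")
            row[f"wrong_predictions_{target}_sd"] = (
                values.std(ddof=1) if len(values) > 1 else (0.0 if len(values) == 1 else float("nan"))
            )
        f = ctrf_scores[ctrf_scores["session_type"] == session_type]
        for rater in ("caregiver", "teacher"):
            fr = f[f["rater"] == rater]
            for subscale in ("attention", "stress"):
                values = fr[f"{subscale}_score"].astype(float)
                key = f"ctrf_{subscale}_{rater}"
                row[f"{key}_mean"] = values.mean() if len(values) else float("nan")
                row[f"{key}_sd"] = (
                    values.std(ddof=1) if len(values) > 1 else (0.0 if len(values) == 1 else float("nan"))
                )
        row["small_n"] = ctrf_scores["participant_id"].nunique() < 2
        rows.append(row)
    return pd.DataFrame(rows)


def load_reference_cohort() -> dict:
    """Bundled summary statistics of the original evaluation cohort (inputs
    to the worked examples, never outputs of this package)."""
    return json.loads(resources.files("sensrec.data").joinpath("reference_cohort.json").read_text())
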