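"""Mamdani fuzzy risk controllers with LOM defuzzification.

Three independent controllers — brightness, temperature, noise — map a crisp
stimulus reading, the duration of the ongoing atypical response, and the
predicted attention and stress levels to a crisp risk value on [0, 10], a
risk category (Low / Medium / High), and a recommended management strategy.

Inference is classical Mamdani: min-conjunction of antecedent memberships,
min-clipping of consequents, pointwise-max aggregation on a fixed output
grid, then defuzzification.  The default defuzzifier is Largest of Maximum
(LOM) — the largest output value whose membership attains the aggregated
maximum — chosen over the centroid because the centroid averages competing
consequents toward Medium Risk, while missing a High Risk state is the
costly error here.  A centroid defuzzifier is kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .membership import Categorical, Gaussian, MembershipFunction, Trapezoid, from_config

__all__ = [
    "LinguisticVariable",
    "FuzzyRule",
    "FuzzyController",
    "RiskAssessment",
    "AggregatedSet",
    "InferenceError",
    "fuzzify",
    "activate",
    "aggregate",
    "defuzzify",
    "stimulus_level",
    "track_duration",
    "compare_defuzzifiers",
    "build_alert",
]

#: Risk term -> short category name.
CATEGORY_OF_TERM = {"Low Risk": "Low", "Medium Risk": "Medium", "High Risk": "High"}
#: Margin for calling a runner-up stimulus term a hybrid level ("moderate-high").
HYBRID_RATIO = 0.5


class InferenceError(RuntimeError):
    """Raised when inference inputs are inconsistent with the rule base."""


@dataclass(frozen=True)
class LinguisticVariable:
    """A named fuzzy variable: an ordered term set with one MF per term.

    Numeric variables clamp inputs to their universe before fuzzification and
    must satisfy the coverage invariant (max membership over terms >= 0.5
    everywhere on the universe).  Categorical variables (attention, stress)
    carry crisp indicator terms and no universe.
    """

    name: str
    terms: dict[str, MembershipFunction]
    order: tuple[str, ...]
    universe: Optional[tuple[float, float]] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if set(self.order) != set(self.terms):
            raise ValueError(f"{self.name}: term order {self.order} does not match terms {sorted(self.terms)}")
        if self.universe is not None and self.universe[0] >= self.universe[1]:
            raise ValueError(f"{self.name}: empty universe {self.universe}")

    @property
    def categorical(self) -> bool:
        return self.universe is None

    def check_coverage(self, n: int = 601, minimum: float = 0.5) -> float:
        """Smallest max-over-terms membership on the universe grid."""
        if self.categorical:
            return 1.0
        xs = np.linspace(self.universe[0], self.universe[1], n)
        cover = np.max([self.terms[t].mu_array(xs) for t in self.order], axis=0)
        worst = float(cover.min())
        if worst < minimum:
            at = float(xs[int(cover.argmin())])
            raise ValueError(
                f"{self.name}: term coverage drops to {worst:.3f} at {at:.3g} (must stay >= {minimum})"
            )
        return worst

    def clamp(self, x: float) -> float:
        lo, hi = self.universe
        return float(min(max(x, lo), hi))

    @classmethod
    def from_config(cls, spec: dict) -> "LinguisticVariable":
        if spec.get("categorical"):
            order = tuple(spec["order"])
            return cls(spec["name"], {t: Categorical(t) for t in order}, order)
        return cls(
            spec["name"],
            {t: from_config(s) for t, s in spec["terms"].items()},
            tuple(spec["order"]),
            tuple(spec["universe"]),
            spec.get("unit"),
        )


@dataclass(frozen=True)
class FuzzyRule:
    """IF <conjunction of (variable is term)> THEN risk is <consequent>."""

    antecedents: dict[str, str]
    consequent: str

    def __post_init__(self) -> None:
        if not self.antecedents:
            raise ValueError("rule must have at least one antecedent")
        if self.consequent not in CATEGORY_OF_TERM:
            raise ValueError(f"consequent must be a risk term, got {self.consequent!r}")

    def matches(self, combo: dict[str, str]) -> bool:
        return all(combo.get(var) == term for var, term in self.antecedents.items())


@dataclass
class AggregatedSet:
    """Output fuzzy set sampled on a fixed grid; ``empty`` if no rule fired."""

    xs: np.ndarray
    mus: np.ndarray
    empty: bool = False


@dataclass
class RiskAssessment:
    """Crisp risk with its category, triggering stimulus level and strategy."""

    risk: float
    category: str  # {"Low", "Medium", "High"}
    modality: str
    stimulus_level: str  # e.g. "high", "moderate-high"
    strategy: str = ""
    no_rule_fired: bool = False

    def as_dict(self) -> dict:
        return {
            "risk": self.risk,
            "category": self.category,
            "modality": self.modality,
            "stimulus_level": self.stimulus_level,
            "strategy": self.strategy,
            "no_rule_fired": self.no_rule_fired,
        }


def fuzzify(variable: LinguisticVariable, x) -> dict[str, float]:
    """Membership degree of ``x`` in every term of ``variable``."""
    if variable.categorical:
        if x not in variable.terms:
            raise InferenceError(f"{variable.name}: unknown level {x!r} (expected one of {variable.order})")
        return {t: variable.terms[t].mu(x) for t in variable.order}
    x = variable.clamp(float(x))
    return {t: variable.terms[t].mu(x) for t in variable.order}


def activate(rule: FuzzyRule, fuzzified: dict[str, dict[str, float]]) -> float:
    """Rule strength: min over antecedent membership degrees."""
    strength = 1.0
    for var, term in rule.antecedents.items():
        if var not in fuzzified:
            raise InferenceError(f"rule references variable {var!r} absent from the inputs")
        strength = min(strength, fuzzified[var].get(term, 0.0))
    return strength


def aggregate(
    activations: Sequence[tuple[FuzzyRule, float]],
    output: LinguisticVariable,
    grid_points: int = 1001,
) -> AggregatedSet:
    """Pointwise max of consequent MFs clipped at their rule strengths."""
    if not activations:
        raise InferenceError("aggregate requires at least one rule activation")
    xs = np.linspace(output.universe[0], output.universe[1], grid_points)
    mus = np.zeros_like(xs)
    for rule, strength in activations:
        if strength <= 0.0:
            continue
        mus = np.maximum(mus, np.minimum(output.terms[rule.consequent].mu_array(xs), strength))
    return AggregatedSet(xs, mus, empty=bool(mus.max() == 0.0))


def defuzzify(agg: AggregatedSet, method: str = "LOM") -> float:
    """Crisp value of an aggregated set.

    ``LOM``: largest x at which the membership attains its maximum.
    ``centroid``: sum(x mu) / sum(mu) on the grid.
    """
    if agg.empty:
        raise InferenceError("cannot defuzzify an empty aggregated set")
    if method == "LOM":
        peak = agg.mus.max()
        return float(agg.xs[agg.mus >= peak - 1e-12][-1])
    if method == "centroid":
        return float((agg.xs * agg.mus).sum() / agg.mus.sum())
    raise ValueError(f"unknown defuzzification method {method!r}")


def stimulus_level(degrees: dict[str, float], order: tuple[str, ...]) -> str:
    """Linguistic stimulus level: the argmax term, reported as a hybrid
    (e.g. "moderate-high") when the adjacent runner-up reaches at least
    HYBRID_RATIO of the top membership."""
    ranked = sorted(order, key=lambda t: degrees[t], reverse=True)
    top = ranked[0]
    top_i = order.index(top)
    best_adjacent = None
    for j in (top_i - 1, top_i + 1):
        if 0 <= j < len(order):
            t = order[j]
            if degrees[top] > 0 and degrees[t] / degrees[top] >= HYBRID_RATIO:
                if best_adjacent is None or degrees[t] > degrees[best_adjacent]:
                    best_adjacent = t
    if best_adjacent is None:
        return top.lower()
    pair = sorted((top, best_adjacent), key=order.index)
    return "-".join(t.lower() for t in pair)


class FuzzyController:
    """One modality's 21-rule Mamdani risk controller."""

    def __init__(
        self,
        modality: str,
        stimulus: LinguisticVariable,
        duration: LinguisticVariable,
        attention: LinguisticVariable,
        stress: LinguisticVariable,
        output: LinguisticVariable,
        rules: Sequence[FuzzyRule],
        strategy_catalog: Optional[dict] = None,
        grid_points: int = 1001,
        expected_rule_count: Optional[int] = 21,
        check_coverage: bool = True,
    ):
        self.modality = modality
        self.stimulus = stimulus
        self.duration = duration
        self.attention = attention
        self.stress = stress
        self.output = output
        self.rules = list(rules)
        self.strategy_catalog = strategy_catalog
        self.grid_points = grid_points
        if expected_rule_count is not None and len(self.rules) != expected_rule_count:
            raise ValueError(f"{modality}: expected {expected_rule_count} rules, got {len(self.rules)}")
        if check_coverage:
            for var in (stimulus, duration, output):
                var.check_coverage()
            self._check_reachability()

    def _check_reachability(self) -> None:
        """Every term combination must be consistent with >= 1 rule."""
        for s in self.stimulus.order:
            for d in self.duration.order:
                for a in self.attention.order:
                    for t in self.stress.order:
                        combo = {"stimulus": s, "duration": d, "attention": a, "stress": t}
                        if not any(r.matches(combo) for r in self.rules):
                            raise ValueError(f"{self.modality}: no rule reaches combination {combo}")

    # -- inference ---------------------------------------------------------

    def fuzzify_inputs(self, stimulus: float, duration_s: float, attention: str, stress: str) -> dict:
        if duration_s < 0:
            raise InferenceError("duration must be >= 0 s")
        return {
            "stimulus": fuzzify(self.stimulus, stimulus),
            "duration": fuzzify(self.duration, duration_s),
            "attention": fuzzify(self.attention, attention),
            "stress": fuzzify(self.stress, stress),
        }

    def aggregate(self, fuzzified: dict) -> AggregatedSet:
        activations = [(rule, activate(rule, fuzzified)) for rule in self.rules]
        return aggregate(activations, self.output, self.grid_points)

    def categorize(self, risk: float) -> str:
        """Risk category: argmax output term at the crisp value, ties broken
        toward higher risk (High Risk misses are the costly error)."""
        degrees = [(term, self.output.terms[term].mu(risk)) for term in self.output.order]
        best = max(d for _, d in degrees)
        for term, d in reversed(degrees):
            if d >= best - 1e-12:
                return CATEGORY_OF_TERM[term]
        raise InferenceError("unreachable")  # pragma: no cover

    def strategy_for(self, stimulus_level: str, category: str) -> str:
        if self.strategy_catalog is None:
            return ""
        entry = (
            self.strategy_catalog.get("entries", {})
            .get(self.modality, {})
            .get(stimulus_level, {})
            .get(category)
        )
        if entry is not None:
            return entry
        template = self.strategy_catalog.get("_default", {}).get(category, "")
        return template.format(
            Modality=self.modality.capitalize(), modality=self.modality, level=stimulus_level
        )

    def infer(
        self, stimulus: float, duration_s: float, attention: str, stress: str, method: str = "LOM"
    ) -> RiskAssessment:
        """Full pipeline: fuzzify -> activate all rules -> aggregate ->
        defuzzify -> categorize -> attach strategy text.  Deterministic.

        If no rule fires at all (possible only for non-default rule bases),
        the assessment defaults to Low Risk and is flagged."""
        fuzzified = self.fuzzify_inputs(stimulus, duration_s, attention, stress)
        agg = self.aggregate(fuzzified)
        level = stimulus_level(fuzzified["stimulus"], self.stimulus.order)
        if agg.empty:
            return RiskAssessment(0.0, "Low", self.modality, level, self.strategy_for(level, "Low"), True)
        risk = defuzzify(agg, method)
        category = self.categorize(risk)
        return RiskAssessment(risk, category, self.modality, level, self.strategy_for(level, category))


def track_duration(states: Iterable[tuple[str, str, str]]) -> list[int]:
    """Seconds the atypical condition has lasted, per timestep.

    ``states`` yields per-second ``(attention, stress, stimulus_level)``.
    The atypical condition is (attention low OR stress high) while the
    stimulus level is not plainly moderate; the counter resets to 0 the
    moment the condition clears.
    """
    out: list[int] = []
    run = 0
    for attention, stress, level in states:
        atypical = (attention == "low" or stress == "high") and level != "moderate"
        run = run + 1 if atypical else 0
        out.append(run)
    return out


def compare_defuzzifiers(
    controller: FuzzyController,
    suite: Sequence[dict],
    methods: tuple[str, ...] = ("LOM", "centroid"),
) -> dict[str, float]:
    """Fraction of suite combinations whose risk category matches the
    expected outcome, per defuzzification method."""
    if not suite:
        raise ValueError("defuzzifier comparison suite is empty")
    out = {}
    for method in methods:
        hits = 0
        for case in suite:
            r = controller.infer(
                case["stimulus"], case["duration"], case["attention"], case["stress"], method=method
            )
            hits += r.category == case["expected"]
        out[method] = hits / len(suite)
    return out


def build_alert(
    assessment: RiskAssessment, subscription: Optional[str], timestamp: Optional[int] = None
) -> Optional[dict]:
    """Message payload for a High-Risk assessment, or None.

    A payload is produced iff the category is High and a subscription phone
    number is active; transport (SMS gateway) is outside this package.
    """
    if subscription is not None:
        digits = subscription.replace(" ", "").replace("-", "").lstrip("+")
        if not digits.isdigit() or len(digits) < 6:
            raise ValueError(f"malformed phone number {subscription!r}")
    if assessment.category != "High" or subscription is None:
        return None
    return {
        "recipient": subscription,
        "modality": assessment.modality,
        "category": assessment.category,
        "strategy": assessment.strategy,
        "timestamp": timestamp,
    }
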