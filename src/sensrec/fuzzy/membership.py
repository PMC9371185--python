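"""Membership functions for the fuzzy controllers.

Two parametric shapes are supported for numeric universes — trapezoids
(piecewise linear 0 -> 1 -> 0; triangles and shoulders are degenerate cases)
and Gaussians exp(-(x-m)^2 / (2 sigma^2)) — plus a categorical indicator for
crisp term inputs such as the predicted attention and stress levels.  All
parameter validation happens at construction time; evaluation never raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = ["Trapezoid", "Gaussian", "Categorical", "MembershipFunction", "mu"]


@dataclass(frozen=True)
class Trapezoid:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"trapezoid requires a <= b <= c <= d, got {(self.a, self.b, self.c, self.d)}")
        if self.a == self.d:
            raise ValueError("degenerate trapezoid with zero support")

    def mu(self, x: float) -> float:
        x = float(x)
        if x < self.a or x > self.d:
            return 0.0
        rise = 1.0 if self.b == self.a else min((x - self.a) / (self.b - self.a), 1.0)
        fall = 1.0 if self.d == self.c else min((self.d - x) / (self.d - self.c), 1.0)
        return max(0.0, min(rise, fall, 1.0))

    def mu_array(self, xs: np.ndarray) -> np.ndarray:
        xs = np.asarray(xs, dtype=float)
        rise = np.ones_like(xs) if self.b == self.a else (xs - self.a) / (self.b - self.a)
        fall = np.ones_like(xs) if self.d == self.c else (self.d - xs) / (self.d - self.c)
        out = np.minimum(np.minimum(rise, fall), 1.0)
        out[(xs < self.a) | (xs > self.d)] = 0.0
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class Gaussian:
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"gaussian sigma must be > 0, got {self.sigma}")

    def mu(self, x: float) -> float:
        z = (float(x) - self.mean) / self.sigma
        return math.exp(-0.5 * z * z)

    def mu_array(self, xs: np.ndarray) -> np.ndarray:
        z = (np.asarray(xs, dtype=float) - self.mean) / self.sigma
        return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class Categorical:
    """Indicator membership for crisp symbolic inputs (degree 1 on a match)."""

    term: str

    def mu(self, x) -> float:
        return 1.0 if x == self.term else 0.0


MembershipFunction = Union[Trapezoid, Gaussian, Categorical]


def mu(mf: MembershipFunction, x) -> float:
    """Membership degree of ``x`` under ``mf``; always in [0, 1]."""
    return mf.mu(x)


def from_config(spec: dict) -> MembershipFunction:
    """Build a membership function from its JSON description."""
    shape = spec["shape"]
    if shape == "trapezoid":
        return Trapezoid(*spec["params"])
    if shape == "gaussian":
        return Gaussian(*spec["params"])
    if shape == "categorical":
        return Categorical(spec["params"][0] if isinstance(spec["params"], list) else spec["params"])
    raise ValueError(f"unknown membership shape {shape!r}")
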