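"""Fuzzy diagnosis of symptomatic complex behaviors.

The crisp input is the *frequency* ``f`` of a complex behavior: the fraction
of a 15-s observation window covered by its related atomic behaviors
(``0 <= f <= 1``).  ``f`` is fuzzified over the linguistic terms
``{Seldom, Consistent, Most}``; a uniform rule matrix maps ``Seldom`` to
``Normal`` and both ``Consistent`` and ``Most`` to ``Abnormal`` for all three
complex behaviors.  Mamdani min-implication clips each output set at its rule
activation, the clipped sets are max-combined, and the combined shape is
defuzzified by center of gravity (CoG).  The crisp diagnosis index is finally
compared against a per-behavior heuristic threshold: strictly above threshold
means ``Abnormal``.

Default membership functions (all breakpoints configurable):

* frequency universe ``[0, 1]``: Seldom = trapezoid (0, 0, 0.15, 0.45),
  Consistent = triangle (0.15, 0.45, 0.75), Most = trapezoid (0.3, 0.45, 1, 1).
  With these sets a frequency of 0.3 is 50% Seldom and 50% Consistent (and
  not at all Most).  Most saturates at 0.45, where Consistent begins to
  decline: because Consistent and Most share the Abnormal consequent, the
  max-aggregated Abnormal activation is then non-decreasing in f, which
  makes the defuzzified diagnosis index monotone — with a Most set rising
  only after Consistent's peak the index would dip in the mid range.
* diagnosis-index universe ``[0, 3]``: Normal = trapezoid (0, 0, 0.5, 1.5),
  Abnormal = trapezoid (1.0, 2.0, 3, 3).  The pure-Normal centroid (~0.542)
  and pure-Abnormal centroid (~2.222) bracket both decision thresholds
  (vocalization 1.0; destructive and exploratory 1.5), so the thresholds are
  discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .events import ComplexBehavior, SymptomState

__all__ = [
    "FuzzySet",
    "trapezoid",
    "triangle",
    "LinguisticVariable",
    "FuzzyRuleBase",
    "DiagnosisConfig",
    "AggregatedShape",
    "default_frequency_variable",
    "default_diagnosis_variable",
    "default_rule_base",
    "fuzzify",
    "infer",
    "defuzzify_cog",
    "decide",
    "FuzzyEngine",
]


@dataclass(frozen=True)
class FuzzySet:
    """A trapezoidal membership function with breakpoints ``a <= b <= c <= d``.

    Triangles are trapezoids with ``b == c``.  Membership ramps linearly from
    0 at ``a`` up to 1 on the plateau ``[b, c]`` and back to 0 at ``d``;
    degenerate ramps (``a == b`` or ``c == d``) are vertical edges.
    """

    name: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(
                f"breakpoints must satisfy a <= b <= c <= d, got "
                f"({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def membership(self, x):
        x = np.asarray(x, dtype=float)
        mu = np.zeros_like(x)
        # rising ramp
        if self.b > self.a:
            rising = (x > self.a) & (x < self.b)
            mu = np.where(rising, (x - self.a) / (self.b - self.a), mu)
        # plateau (closed on both ends)
        mu = np.where((x >= self.b) & (x <= self.c), 1.0, mu)
        # falling ramp
        if self.d > self.c:
            falling = (x > self.c) & (x < self.d)
            mu = np.where(falling, (self.d - x) / (self.d - self.c), mu)
        return mu if mu.ndim else float(mu)


def trapezoid(name: str, a: float, b: float, c: float, d: float) -> FuzzySet:
    return FuzzySet(name, a, b, c, d)


def triangle(name: str, a: float, b: float, c: float) -> FuzzySet:
    return FuzzySet(name, a, b, b, c)


@dataclass(frozen=True)
class LinguisticVariable:
    """A named crisp universe with a family of fuzzy sets over it."""

    name: str
    universe: tuple
    sets: tuple

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ValueError(f"universe must satisfy lo < hi, got ({lo}, {hi})")
        for s in self.sets:
            if s.a < lo - 1e-12 or s.d > hi + 1e-12:
                raise ValueError(
                    f"set {s.name!r} breakpoints [{s.a}, {s.d}] outside "
                    f"universe [{lo}, {hi}]"
                )

    def set_named(self, name: str) -> FuzzySet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(f"{self.name!r} has no set named {name!r}")

    def fuzzify(self, x: float) -> dict:
        lo, hi = self.universe
        if not (lo <= x <= hi):
            raise ValueError(
                f"crisp value {x} outside universe [{lo}, {hi}] of {self.name!r}"
            )
        return {s.name: float(s.membership(x)) for s in self.sets}


def default_frequency_variable() -> LinguisticVariable:
    """The input variable: complex-behavior frequency over ``[0, 1]``."""
    return LinguisticVariable(
        name="frequency",
        universe=(0.0, 1.0),
        sets=(
            trapezoid("Seldom", 0.0, 0.0, 0.15, 0.45),
            triangle("Consistent", 0.15, 0.45, 0.75),
            trapezoid("Most", 0.3, 0.45, 1.0, 1.0),
        ),
    )


def default_diagnosis_variable() -> LinguisticVariable:
    """The output variable: diagnosis index over ``[0, 3]``."""
    return LinguisticVariable(
        name="diagnosis_index",
        universe=(0.0, 3.0),
        sets=(
            trapezoid("Normal", 0.0, 0.0, 0.5, 1.5),
            trapezoid("Abnormal", 1.0, 2.0, 3.0, 3.0),
        ),
    )


@dataclass(frozen=True)
class FuzzyRuleBase:
    """Per-behavior mapping from input term to output term.

    The default matrix is uniform: Seldom -> Normal, Consistent -> Abnormal,
    Most -> Abnormal, identically for all three complex behaviors.
    """

    rules: Mapping

    def consequents(self, behavior: ComplexBehavior) -> Mapping:
        behavior = ComplexBehavior(behavior)
        if behavior not in self.rules:
            raise KeyError(f"no rules for behavior {behavior.value!r}")
        return self.rules[behavior]


def default_rule_base() -> FuzzyRuleBase:
    row = {"Seldom": "Normal", "Consistent": "Abnormal", "Most": "Abnormal"}
    return FuzzyRuleBase(rules={b: dict(row) for b in ComplexBehavior})


@dataclass(frozen=True)
class DiagnosisConfig:
    """Decision thresholds and CoG integration resolution.

    ``resolution`` is the quadrature step as a fraction of the output
    universe span (default 1e-3).  Thresholds must lie inside the output
    universe; the decision is strict: index > threshold => Abnormal.
    """

    thresholds: Mapping = field(
        default_factory=lambda: {
            ComplexBehavior.VOCALIZATION: 1.0,
            ComplexBehavior.DESTRUCTIVE: 1.5,
            ComplexBehavior.EXPLORATORY: 1.5,
        }
    )
    resolution: float = 1e-3


@dataclass(frozen=True)
class AggregatedShape:
    """A max-combined, activation-clipped output membership sampled on a grid."""

    xs: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        if self.xs.shape != self.mu.shape:
            raise ValueError("xs and mu must have equal shape")
        if np.any(self.mu < -1e-12) or np.any(self.mu > 1 + 1e-12):
            raise ValueError("membership values must lie in [0, 1]")


def fuzzify(f: float, variable: LinguisticVariable | None = None) -> dict:
    """Membership degrees of frequency ``f`` over {Seldom, Consistent, Most}."""
    variable = variable if variable is not None else default_frequency_variable()
    return variable.fuzzify(f)


def infer(
    memberships: Mapping,
    behavior: ComplexBehavior,
    rule_base: FuzzyRuleBase | None = None,
    output_variable: LinguisticVariable | None = None,
    resolution: float = 1e-3,
) -> AggregatedShape:
    """Mamdani inference: clip each output set at the max activation of the
    rules concluding it, then max-combine the clipped sets."""
    rule_base = rule_base if rule_base is not None else default_rule_base()
    output_variable = (
        output_variable if output_variable is not None else default_diagnosis_variable()
    )
    consequents = rule_base.consequents(behavior)
    activations: dict = {}
    for input_term, degree in memberships.items():
        if input_term not in consequents:
            raise KeyError(
                f"input term {input_term!r} has no consequent for "
                f"{ComplexBehavior(behavior).value!r}"
            )
        out = consequents[input_term]
        activations[out] = max(activations.get(out, 0.0), float(degree))

    lo, hi = output_variable.universe
    n = int(round((hi - lo) / (resolution * (hi - lo)))) + 1
    xs = np.linspace(lo, hi, n)
    mu = np.zeros_like(xs)
    for out_name, level in activations.items():
        if level <= 0.0:
            continue
        clipped = np.minimum(output_variable.set_named(out_name).membership(xs), level)
        mu = np.maximum(mu, clipped)
    return AggregatedShape(xs=xs, mu=mu)


def defuzzify_cog(shape: AggregatedShape) -> float:
    """Center of gravity of the aggregated shape by trapezoidal quadrature."""
    area = np.trapezoid(shape.mu, shape.xs)
    if area <= 0.0:
        raise ValueError("cannot defuzzify a zero-area shape: no rule fired")
    return float(np.trapezoid(shape.xs * shape.mu, shape.xs) / area)


def decide(
    index: float,
    behavior: ComplexBehavior,
    config: DiagnosisConfig | None = None,
) -> SymptomState:
    """Threshold the crisp diagnosis index (strictly greater => Abnormal)."""
    config = config if config is not None else DiagnosisConfig()
    behavior = ComplexBehavior(behavior)
    if behavior not in config.thresholds:
        raise KeyError(f"no threshold configured for {behavior.value!r}")
    threshold = config.thresholds[behavior]
    return SymptomState.ABNORMAL if index > threshold else SymptomState.NORMAL


@dataclass(frozen=True)
class FuzzyEngine:
    """The complete fuzzy function F(f): fuzzify, infer, defuzzify, decide."""

    input_variable: LinguisticVariable = field(default_factory=default_frequency_variable)
    output_variable: LinguisticVariable = field(default_factory=default_diagnosis_variable)
    rule_base: FuzzyRuleBase = field(default_factory=default_rule_base)
    config: DiagnosisConfig = field(default_factory=DiagnosisConfig)

    def index(self, f: float, behavior: ComplexBehavior) -> float:
        memberships = self.input_variable.fuzzify(f)
        shape = infer(
            memberships,
            behavior,
            self.rule_base,
            self.output_variable,
            resolution=self.config.resolution,
        )
        return defuzzify_cog(shape)

    def diagnose(self, f: float, behavior: ComplexBehavior):
        """Return ``(crisp index, SymptomState)`` for frequency ``f``."""
        idx = self.index(f, behavior)
        return idx, decide(idx, behavior, self.config)
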