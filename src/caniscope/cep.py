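"""Complex event processing over posture streams.

Two event-processing networks (EPNs) sit on top of the Level-1 posture
stream:

* the **atomic-behavior EPN** slides a 2-s window in 1-s steps and applies
  two rule kinds:

  - ``repeat`` (C1): the same posture is maintained without change for the
    whole window (>= 2 consecutive identical 1-Hz posture events) — e.g.
    ``Digging`` from repeated ``Dig``;
  - ``follow`` (C2): an ordered pair across sensors — a body ``Walk`` (or
    ``Stand``) followed strictly later by a head ``Down`` yields
    ``Sniffing``.

  Matched posture events are *consumed* per output class so the same
  posture pair cannot back two atomic events of one class.

* the **complex-behavior EPN** evaluates every complex rule on consecutive
  tumbling 15-s windows: the *frequency* f of a complex behavior is the
  fraction of the window covered by the union of its related atomic-behavior
  intervals, and the fuzzy engine turns f into a Normal/Abnormal symptom
  state.

Everything in this module is deterministic; multi-subject channels are
processed per subject independently and merged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .events import (
    AtomicBehavior,
    AtomicBehaviorEvent,
    BODY_POSTURES,
    ComplexBehavior,
    ComplexBehaviorEvent,
    EventChannel,
    HEAD_POSTURES,
    Level,
    Posture,
    PostureEvent,
    Sensor,
)
from .fuzzy import FuzzyEngine

__all__ = [
    "RuleKind",
    "PatternRule",
    "RuleSet",
    "CepConfig",
    "FrequencyObservation",
    "default_rule_set",
    "match_c1",
    "match_c2",
    "scan_atomic",
    "coverage_fraction",
    "detect_complex",
    "run_hierarchy",
    "rule_set_to_json",
    "rule_set_from_json",
]


class RuleKind(str, Enum):
    REPEAT_C1 = "repeat_c1"
    FOLLOW_C2 = "follow_c2"
    AGGREGATE_A = "aggregate_a"


@dataclass(frozen=True)
class PatternRule:
    """One CEP pattern rule.

    ``repeat_c1``: ``posture`` repeated through a ``window_s`` window.
    ``follow_c2``: any posture in ``first`` followed strictly later by
    ``second`` (across sensors) within ``window_s``.
    ``aggregate_a``: coverage of ``operands`` atomic classes over a
    ``window_s`` window, diagnosed by the fuzzy engine.
    """

    kind: RuleKind
    output: "AtomicBehavior | ComplexBehavior"
    window_s: float
    posture: "Posture | None" = None
    first: frozenset = frozenset()
    second: "Posture | None" = None
    operands: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", RuleKind(self.kind))
        if self.window_s <= 0:
            raise ValueError(f"window_s must be positive, got {self.window_s}")
        if self.kind is RuleKind.REPEAT_C1:
            if self.posture is None:
                raise ValueError("repeat_c1 rule needs an operand posture")
            object.__setattr__(self, "output", AtomicBehavior(self.output))
        elif self.kind is RuleKind.FOLLOW_C2:
            if not self.first or self.second is None:
                raise ValueError("follow_c2 rule needs 'first' classes and 'second'")
            object.__setattr__(self, "output", AtomicBehavior(self.output))
        else:
            if not self.operands:
                raise ValueError("aggregate_a rule needs atomic operand classes")
            object.__setattr__(self, "output", ComplexBehavior(self.output))
            object.__setattr__(
                self, "operands", frozenset(AtomicBehavior(o) for o in self.operands)
            )

    @property
    def sensor(self) -> "Sensor | None":
        """Sensor a C1 rule listens to (derived from its operand posture)."""
        if self.kind is not RuleKind.REPEAT_C1:
            return None
        return Sensor.HEAD if self.posture in HEAD_POSTURES else Sensor.BODY


@dataclass(frozen=True)
class RuleSet:
    """The atomic (C1/C2) and complex (A) rules of the behavior hierarchy."""

    atomic: tuple
    complex: tuple

    def __post_init__(self) -> None:
        produced = {r.output for r in self.atomic}
        for rule in self.complex:
            missing = rule.operands - produced
            if missing:
                raise ValueError(
                    f"complex rule {rule.output.value!r} uses atomic classes "
                    f"{sorted(m.value for m in missing)} produced by no rule"
                )


def default_rule_set() -> RuleSet:
    """The standard rule set: seven C1 rules, Sniffing as C2, three A rules."""
    c1 = [
        (Posture.WALK, AtomicBehavior.WALKING),
        (Posture.LIE, AtomicBehavior.LYING),
        (Posture.SIT, AtomicBehavior.SITTING),
        (Posture.STAND, AtomicBehavior.STANDING),
        (Posture.DIG, AtomicBehavior.DIGGING),
        (Posture.JUMP, AtomicBehavior.ESCAPING),
        (Posture.BARK, AtomicBehavior.BARKING),
    ]
    atomic = tuple(
        PatternRule(kind=RuleKind.REPEAT_C1, output=out, window_s=2.0, posture=p)
        for p, out in c1
    ) + (
        PatternRule(
            kind=RuleKind.FOLLOW_C2,
            output=AtomicBehavior.SNIFFING,
            window_s=2.0,
            first=frozenset({Posture.WALK, Posture.STAND}),
            second=Posture.DOWN,
        ),
    )
    complex_rules = (
        PatternRule(
            kind=RuleKind.AGGREGATE_A,
            output=ComplexBehavior.DESTRUCTIVE,
            window_s=15.0,
            operands=frozenset({AtomicBehavior.ESCAPING, AtomicBehavior.DIGGING}),
        ),
        PatternRule(
            kind=RuleKind.AGGREGATE_A,
            output=ComplexBehavior.EXPLORATORY,
            window_s=15.0,
            operands=frozenset({AtomicBehavior.WALKING, AtomicBehavior.SNIFFING}),
        ),
        PatternRule(
            kind=RuleKind.AGGREGATE_A,
            output=ComplexBehavior.VOCALIZATION,
            window_s=15.0,
            operands=frozenset({AtomicBehavior.BARKING}),
        ),
    )
    return RuleSet(atomic=atomic, complex=complex_rules)


@dataclass(frozen=True)
class CepConfig:
    """Engine stepping and frequency-mode configuration.

    ``frequency_mode='coverage'`` (default) measures f as interval-union
    coverage of the window; ``'count'`` instead counts matched events and
    normalizes by the window's 1-Hz event capacity.
    """

    atomic_step_s: float = 1.0
    frequency_mode: str = "coverage"

    def __post_init__(self) -> None:
        if self.atomic_step_s <= 0:
            raise ValueError("atomic_step_s must be positive")
        if self.frequency_mode not in ("coverage", "count"):
            raise ValueError(f"unknown frequency_mode {self.frequency_mode!r}")


@dataclass(frozen=True)
class FrequencyObservation:
    """Fraction of an observation window covered by given atomic classes."""

    behavior: "ComplexBehavior | None"
    t_start: float
    window_s: float
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"frequency must lie in [0, 1], got {self.f}")


# ---------------------------------------------------------------------------
# Atomic-behavior EPN
# ---------------------------------------------------------------------------

def _sensor_of(posture: Posture) -> Sensor:
    return Sensor.HEAD if posture in HEAD_POSTURES else Sensor.BODY


def match_c1(l1_view, rule: PatternRule):
    """Match a repeat (C1) rule on a 2-s window of posture events.

    The view must contain one subject's events.  A match requires at least
    two consecutive events of the operand posture on the rule's sensor, with
    no different posture from that sensor in between; ``ts`` is the first
    matched event's timestamp and ``te = ts + window_s``.  Returns the
    emitted event or ``None``.
    """
    if rule.kind is not RuleKind.REPEAT_C1:
        raise ValueError(f"match_c1 requires a repeat_c1 rule, got {rule.kind.value}")
    run: list = []
    for ev in l1_view:
        if ev.sensor_id is not rule.sensor:
            continue
        if ev.posture is rule.posture:
            run.append(ev)
            if len(run) >= 2:
                # extend the run to the window end before emitting
                continue
        else:
            if len(run) >= 2:
                break
            run = []
    if len(run) >= 2:
        first = run[0]
        return AtomicBehaviorEvent(
            subject_id=first.subject_id,
            behavior=rule.output,
            ts=first.t,
            te=first.t + rule.window_s,
        )
    return None


def match_c2(l1_view, rule: PatternRule):
    """Match a follow (C2) rule: a ``first``-class body posture followed
    strictly later by the ``second`` head posture within the window."""
    if rule.kind is not RuleKind.FOLLOW_C2:
        raise ValueError(f"match_c2 requires a follow_c2 rule, got {rule.kind.value}")
    second_sensor = _sensor_of(rule.second)
    for ev in l1_view:
        if ev.posture in rule.first:
            for later in l1_view:
                if (
                    later.sensor_id is second_sensor
                    and later.posture is rule.second
                    and later.t > ev.t
                ):
                    return AtomicBehaviorEvent(
                        subject_id=ev.subject_id,
                        behavior=rule.output,
                        ts=ev.t,
                        te=ev.t + rule.window_s,
                    )
    return None


def _scan_atomic_subject(events, rules, step_s: float) -> list:
    """Windowed scan with per-output-class event consumption.

    Consumed events are invisible to further matches of the same output
    class but still act as 'different posture' interrupters for C1 runs of
    other classes.
    """
    if not events:
        return []
    consumed: dict = {rule.output: set() for rule in rules}
    out: list = []
    t0 = math.floor(events[0].t)
    t_end = events[-1].t
    start = float(t0)
    while start <= t_end:
        window = [ev for ev in events if start <= ev.t < start + 2.0]
        for rule in rules:
            taken = consumed[rule.output]
            view = [ev for ev in window if id(ev) not in taken]
            if rule.kind is RuleKind.REPEAT_C1:
                matched = match_c1(view, rule)
                if matched is not None:
                    # consume the events of the matched run
                    run_started = False
                    for ev in view:
                        if ev.sensor_id is not rule.sensor:
                            continue
                        if ev.posture is rule.posture and (
                            run_started or ev.t == matched.ts
                        ):
                            run_started = True
                            taken.add(id(ev))
                        elif run_started:
                            break
                    out.append(matched)
            elif rule.kind is RuleKind.FOLLOW_C2:
                matched = match_c2(view, rule)
                if matched is not None:
                    second_sensor = _sensor_of(rule.second)
                    first_ev = next(
                        ev for ev in view
                        if ev.posture in rule.first and ev.t == matched.ts
                    )
                    second_ev = next(
                        ev for ev in view
                        if ev.sensor_id is second_sensor
                        and ev.posture is rule.second
                        and ev.t > matched.ts
                    )
                    taken.add(id(first_ev))
                    taken.add(id(second_ev))
                    out.append(matched)
        start += step_s
    return out


def scan_atomic(
    l1_channel: EventChannel,
    rule_set: "RuleSet | None" = None,
    config: "CepConfig | None" = None,
) -> EventChannel:
    """Slide the 2-s atomic window in 1-s steps over the L1 stream.

    Each posture event contributes to at most one atomic event per output
    class.  Subjects are processed independently.
    """
    if l1_channel.level is not Level.L1:
        raise ValueError("scan_atomic expects an L1 channel")
    rule_set = rule_set if rule_set is not None else default_rule_set()
    config = config if config is not None else CepConfig()
    atomic_rules = [r for r in rule_set.atomic if r.kind is not RuleKind.AGGREGATE_A]
    l2 = EventChannel(level=Level.L2)
    for subject in l1_channel.subjects():
        events = [ev for ev in l1_channel if ev.subject_id == subject]
        for matched in _scan_atomic_subject(events, atomic_rules, config.atomic_step_s):
            l2.publish(matched)
    return l2


# ---------------------------------------------------------------------------
# Complex-behavior EPN
# ---------------------------------------------------------------------------

def _union_length(intervals) -> float:
    total = 0.0
    last_end = -math.inf
    for lo, hi in sorted(intervals):
        if hi <= last_end:
            continue
        total += hi - max(lo, last_end)
        last_end = hi
    return total


def coverage_fraction(
    l2_view,
    atomic_classes,
    t_start: float,
    window_s: float = 15.0,
    behavior: "ComplexBehavior | None" = None,
    mode: str = "coverage",
) -> FrequencyObservation:
    """Fraction of ``[t_start, t_start + window_s)`` covered by the union of
    intervals of events whose class is in ``atomic_classes``.

    Overlapping intervals are counted once; intervals are clipped to the
    window.  ``mode='count'`` instead counts matching events normalized by
    the window's 1-Hz capacity (capped at 1).
    """
    atomic_classes = frozenset(AtomicBehavior(c) for c in atomic_classes)
    t_end = t_start + window_s
    matching = [
        ev for ev in l2_view
        if ev.behavior in atomic_classes and ev.te > t_start and ev.ts < t_end
    ]
    if mode == "count":
        f = min(1.0, len(matching) / window_s)
    else:
        intervals = [(max(ev.ts, t_start), min(ev.te, t_end)) for ev in matching]
        f = _union_length(intervals) / window_s
    return FrequencyObservation(
        behavior=behavior, t_start=t_start, window_s=window_s, f=min(1.0, max(0.0, f))
    )


def detect_complex(
    l2_channel: EventChannel,
    rule_set: "RuleSet | None" = None,
    fuzzy_engine: "FuzzyEngine | None" = None,
    config: "CepConfig | None" = None,
) -> EventChannel:
    """Evaluate every complex rule on consecutive tumbling 15-s windows.

    One complex-behavior event is emitted per (window, behavior); the
    symptom state comes from the fuzzy engine applied to the window's
    frequency observation.
    """
    if l2_channel.level is not Level.L2:
        raise ValueError("detect_complex expects an L2 channel")
    rule_set = rule_set if rule_set is not None else default_rule_set()
    fuzzy_engine = fuzzy_engine if fuzzy_engine is not None else FuzzyEngine()
    config = config if config is not None else CepConfig()
    l3 = EventChannel(level=Level.L3)
    for subject in l2_channel.subjects():
        events = [ev for ev in l2_channel if ev.subject_id == subject]
        if not events:
            continue
        window_s = rule_set.complex[0].window_s if rule_set.complex else 15.0
        first = math.floor(min(ev.ts for ev in events) / window_s) * window_s
        last = max(ev.te for ev in events)
        n_windows = max(1, math.ceil((last - first) / window_s))
        for k in range(n_windows):
            w0 = first + k * window_s
            for rule in rule_set.complex:
                obs = coverage_fraction(
                    events,
                    rule.operands,
                    t_start=w0,
                    window_s=rule.window_s,
                    behavior=rule.output,
                    mode=config.frequency_mode,
                )
                _, state = fuzzy_engine.diagnose(obs.f, rule.output)
                l3.publish(
                    ComplexBehaviorEvent(
                        subject_id=subject,
                        behavior=rule.output,
                        d=state,
                        ts=w0,
                        te=w0 + rule.window_s,
                    )
                )
    return l3


def run_hierarchy(
    l1_channel: EventChannel,
    rule_set: "RuleSet | None" = None,
    fuzzy_engine: "FuzzyEngine | None" = None,
    config: "CepConfig | None" = None,
):
    """Full hierarchy: L1 postures -> (L2 atomic, L3 complex) channels."""
    rule_set = rule_set if rule_set is not None else default_rule_set()
    l2 = scan_atomic(l1_channel, rule_set, config)
    l3 = detect_complex(l2, rule_set, fuzzy_engine, config)
    return l2, l3


# ---------------------------------------------------------------------------
# Rule-set (de)serialization
# ---------------------------------------------------------------------------

def rule_set_to_json(rule_set: RuleSet, path=None) -> str:
    """Serialize a rule set to a human-editable JSON document."""
    def encode(rule: PatternRule) -> dict:
        rec = {"kind": rule.kind.value, "output": rule.output.value,
               "window_s": rule.window_s}
        if rule.kind is RuleKind.REPEAT_C1:
            rec["posture"] = rule.posture.value
        elif rule.kind is RuleKind.FOLLOW_C2:
            rec["first"] = sorted(p.value for p in rule.first)
            rec["second"] = rule.second.value
        else:
            rec["operands"] = sorted(o.value for o in rule.operands)
        return rec

    doc = json.dumps(
        {
            "atomic": [encode(r) for r in rule_set.atomic],
            "complex": [encode(r) for r in rule_set.complex],
        },
        indent=2,
    )
    if path is not None:
        Path(path).write_text(doc + "\n")
    return doc


def rule_set_from_json(source) -> RuleSet:
    """Parse a rule set from a JSON string or file path."""
    text = source
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    data = json.loads(text)

    def decode(rec: dict) -> PatternRule:
        kind = RuleKind(rec["kind"])
        common = dict(kind=kind, window_s=float(rec["window_s"]))
        if kind is RuleKind.REPEAT_C1:
            return PatternRule(
                output=AtomicBehavior(rec["output"]),
                posture=Posture(rec["posture"]), **common,
            )
        if kind is RuleKind.FOLLOW_C2:
            return PatternRule(
                output=AtomicBehavior(rec["output"]),
                first=frozenset(Posture(p) for p in rec["first"]),
                second=Posture(rec["second"]), **common,
            )
        return PatternRule(
            output=ComplexBehavior(rec["output"]),
            operands=frozenset(AtomicBehavior(o) for o in rec["operands"]),
            **common,
        )

    return RuleSet(
        atomic=tuple(decode(r) for r in data["atomic"]),
        complex=tuple(decode(r) for r in data["complex"]),
    )
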