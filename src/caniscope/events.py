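"""Typed events for the three-level behavior hierarchy and ordered event channels.

The monitoring pipeline is organised as three event streams:

* Level 1 (L1): instantaneous head/body postures, one per sensor per second.
* Level 2 (L2): atomic behaviors (e.g. ``Sniffing``), spanning a short
  observation interval with explicit start/end times.
* Level 3 (L3): separation-anxiety symptomatic complex behaviors
  (``Destructive``, ``Exploratory``, ``Vocalization``), each carrying a
  ``Normal``/``Abnormal`` symptom state over a 15-second observation window.

Events are immutable value objects; channels keep them sorted by their
primary timestamp (``t`` for L1, ``ts`` for L2/L3).  Timestamps are seconds
since stream start; windows are half-open ``[start, start + length)``.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

__all__ = [
    "Sensor",
    "Posture",
    "AtomicBehavior",
    "ComplexBehavior",
    "SymptomState",
    "Level",
    "HEAD_POSTURES",
    "BODY_POSTURES",
    "L3_OBSERVATION_S",
    "PostureEvent",
    "AtomicBehaviorEvent",
    "ComplexBehaviorEvent",
    "Event",
    "EventChannel",
    "publish",
    "window_view",
    "event_to_dict",
    "event_from_dict",
    "write_events",
    "read_events",
]


class Sensor(str, Enum):
    """Wearable placement: neck-mounted (head) or back-mounted (body)."""

    HEAD = "head"
    BODY = "body"


class Posture(str, Enum):
    """Level-1 pose/motion vocabulary (3 head classes, 6 body classes)."""

    UP = "Up"
    DOWN = "Down"
    BARK = "Bark"
    WALK = "Walk"
    LIE = "Lie"
    SIT = "Sit"
    STAND = "Stand"
    DIG = "Dig"
    JUMP = "Jump"


HEAD_POSTURES = frozenset({Posture.UP, Posture.DOWN, Posture.BARK})
BODY_POSTURES = frozenset(
    {Posture.WALK, Posture.LIE, Posture.SIT, Posture.STAND, Posture.DIG, Posture.JUMP}
)


class AtomicBehavior(str, Enum):
    """Level-2 atomic behavior vocabulary."""

    SNIFFING = "Sniffing"
    ESCAPING = "Escaping"
    BARKING = "Barking"
    WALKING = "Walking"
    LYING = "Lying"
    SITTING = "Sitting"
    STANDING = "Standing"
    DIGGING = "Digging"


class ComplexBehavior(str, Enum):
    """Level-3 symptomatic complex behavior vocabulary."""

    DESTRUCTIVE = "Destructive"
    EXPLORATORY = "Exploratory"
    VOCALIZATION = "Vocalization"


class SymptomState(str, Enum):
    NORMAL = "Normal"
    ABNORMAL = "Abnormal"


class Level(str, Enum):
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"


#: Length of the Level-3 observation window in seconds.
L3_OBSERVATION_S = 15.0


@dataclass(frozen=True)
class PostureEvent:
    """A classified head or body posture at time ``t`` (Level 1)."""

    subject_id: str
    sensor_id: Sensor
    posture: Posture
    t: float

    def __post_init__(self) -> None:
        sensor = Sensor(self.sensor_id)
        posture = Posture(self.posture)
        object.__setattr__(self, "sensor_id", sensor)
        object.__setattr__(self, "posture", posture)
        valid = HEAD_POSTURES if sensor is Sensor.HEAD else BODY_POSTURES
        if posture not in valid:
            raise ValueError(
                f"posture {posture.value!r} is not valid for sensor {sensor.value!r}"
            )
        if self.t < 0:
            raise ValueError(f"timestamp must be non-negative, got {self.t}")

    @property
    def timestamp(self) -> float:
        return self.t


@dataclass(frozen=True)
class AtomicBehaviorEvent:
    """An atomic behavior spanning ``[ts, te]`` (Level 2)."""

    subject_id: str
    behavior: AtomicBehavior
    ts: float
    te: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "behavior", AtomicBehavior(self.behavior))
        if not self.ts < self.te:
            raise ValueError(f"require ts < te, got ts={self.ts}, te={self.te}")

    @property
    def timestamp(self) -> float:
        return self.ts


@dataclass(frozen=True)
class ComplexBehaviorEvent:
    """A complex behavior diagnosis over one 15-s observation window (Level 3)."""

    subject_id: str
    behavior: ComplexBehavior
    d: SymptomState
    ts: float
    te: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "behavior", ComplexBehavior(self.behavior))
        object.__setattr__(self, "d", SymptomState(self.d))
        if not self.ts < self.te:
            raise ValueError(f"require ts < te, got ts={self.ts}, te={self.te}")
        if abs((self.te - self.ts) - L3_OBSERVATION_S) > 1e-6:
            raise ValueError(
                f"complex-behavior events span the {L3_OBSERVATION_S:.0f}-s "
                f"observation interval, got {self.te - self.ts}"
            )

    @property
    def timestamp(self) -> float:
        return self.ts


Event = Union[PostureEvent, AtomicBehaviorEvent, ComplexBehaviorEvent]

_LEVEL_TYPES = {
    Level.L1: PostureEvent,
    Level.L2: AtomicBehaviorEvent,
    Level.L3: ComplexBehaviorEvent,
}


@dataclass
class EventChannel:
    """A time-ordered event stream for one hierarchy level.

    ``publish`` inserts preserving non-decreasing timestamp order (stable for
    ties); duplicates are allowed.  ``window_view`` returns the events in a
    half-open time window without modifying the channel.
    """

    level: Level
    _events: list = field(default_factory=list)
    _keys: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.level = Level(self.level)
        events, self._events, self._keys = list(self._events), [], []
        for ev in events:
            self.publish(ev)

    @property
    def events(self) -> tuple:
        return tuple(self._events)

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self._events)

    def __getitem__(self, i):
        return self._events[i]

    def publish(self, event: Event) -> "EventChannel":
        """Insert ``event``, keeping the channel sorted by primary timestamp."""
        expected = _LEVEL_TYPES[self.level]
        if not isinstance(event, expected):
            raise TypeError(
                f"channel level {self.level.value} accepts {expected.__name__}, "
                f"got {type(event).__name__}"
            )
        key = event.timestamp
        idx = bisect.bisect_right(self._keys, key)
        self._keys.insert(idx, key)
        self._events.insert(idx, event)
        return self

    def window_view(self, t_start: float, length: float) -> list:
        """Events with primary timestamp in ``[t_start, t_start + length)``."""
        if length <= 0:
            raise ValueError(f"window length must be positive, got {length}")
        lo = bisect.bisect_left(self._keys, t_start)
        hi = bisect.bisect_left(self._keys, t_start + length)
        return self._events[lo:hi]

    def subjects(self) -> list:
        seen: dict = {}
        for ev in self._events:
            seen.setdefault(ev.subject_id, None)
        return list(seen)


def publish(event: Event, channel: EventChannel) -> EventChannel:
    """Functional alias for :meth:`EventChannel.publish`."""
    return channel.publish(event)


def window_view(channel: EventChannel, t_start: float, length: float) -> list:
    """Functional alias for :meth:`EventChannel.window_view`."""
    return channel.window_view(t_start, length)


# ---------------------------------------------------------------------------
# JSON-lines serialization
# ---------------------------------------------------------------------------

def event_to_dict(event: Event) -> dict:
    if isinstance(event, PostureEvent):
        return {
            "subject_id": event.subject_id,
            "sensor_id": event.sensor_id.value,
            "posture": event.posture.value,
            "t": event.t,
        }
    if isinstance(event, AtomicBehaviorEvent):
        return {
            "subject_id": event.subject_id,
            "behavior": event.behavior.value,
            "ts": event.ts,
            "te": event.te,
        }
    if isinstance(event, ComplexBehaviorEvent):
        return {
            "subject_id": event.subject_id,
            "behavior": event.behavior.value,
            "d": event.d.value,
            "ts": event.ts,
            "te": event.te,
        }
    raise TypeError(f"not an event: {type(event).__name__}")


def event_from_dict(record: dict) -> Event:
    """Build an event from a mapping; unknown extra keys are ignored."""
    if "posture" in record:
        return PostureEvent(
            subject_id=record["subject_id"],
            sensor_id=Sensor(record["sensor_id"]),
            posture=Posture(record["posture"]),
            t=float(record["t"]),
        )
    if "d" in record:
        return ComplexBehaviorEvent(
            subject_id=record["subject_id"],
            behavior=ComplexBehavior(record["behavior"]),
            d=SymptomState(record["d"]),
            ts=float(record["ts"]),
            te=float(record["te"]),
        )
    if "behavior" in record:
        return AtomicBehaviorEvent(
            subject_id=record["subject_id"],
            behavior=AtomicBehavior(record["behavior"]),
            ts=float(record["ts"]),
            te=float(record["te"]),
        )
    raise ValueError(f"record does not look like an event: {sorted(record)}")


def write_events(events: Iterable[Event], path) -> None:
    """Write events as JSON lines, one event per line."""
    path = Path(path)
    with path.open("w") as fh:
        for ev in events:
            fh.write(json.dumps(event_to_dict(ev)) + "\n")


def read_events(path, level: "Level | None" = None) -> EventChannel:
    """Read a JSON-lines event file into a channel.

    The level is inferred from the first record unless given explicitly.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(event_from_dict(json.loads(line)))
    if level is None:
        if not records:
            raise ValueError(
                "cannot infer level from an empty event file; pass level="
            )
        for lvl, typ in _LEVEL_TYPES.items():
            if isinstance(records[0], typ):
                level = lvl
                break
    channel = EventChannel(level=Level(level))
    for ev in records:
        channel.publish(ev)
    return channel
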