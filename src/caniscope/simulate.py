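"""Synthetic 50 Hz accelerometer scenarios with three-level ground truth.

No public recording of dual-sensor dog streams exists, so the package ships
a generator that emulates them: each posture class has a signal template
(static orientation offset, optional sinusoidal oscillation for motion
classes, i.i.d. Gaussian noise), and scripted behavior timelines expand to
per-second posture labels for both sensors, then to raw six-column sample
logs.  Templates are deliberately minimal — enough for the classes to be
separable in simple statistical features (pairwise some-axis baseline
difference of at least four noise standard deviations by construction), not
a biomechanical gait model.

Ground truth is produced at all three levels: the per-second posture labels
(L1), and the atomic (L2) and complex (L3) event sets obtained by running
the default rule set and fuzzy engine on the intended L1 labels.  By
construction the hierarchy reproduces this truth exactly when fed oracle
posture labels, which is what makes end-to-end pipeline tests possible
without animal data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cep import CepConfig, RuleSet, default_rule_set, run_hierarchy
from .events import (
    AtomicBehavior,
    ComplexBehavior,
    EventChannel,
    Level,
    Posture,
    PostureEvent,
    Sensor,
)
from .fuzzy import FuzzyEngine
from .preprocessing import COLUMNS, RATE_HZ

__all__ = [
    "SignalTemplate",
    "DEFAULT_TEMPLATES",
    "DEFAULT_NOISE_SIGMA",
    "Segment",
    "ScenarioScript",
    "GroundTruth",
    "generate_posture_signal",
    "labels_to_channel",
    "script_to_streams",
    "window_slice_augment",
    "make_training_set",
    "preset_script",
]

#: Default Gaussian noise standard deviation (device units).
DEFAULT_NOISE_SIGMA = 0.03


@dataclass(frozen=True)
class SignalTemplate:
    """Per-posture signal recipe: orientation baseline + oscillation + noise."""

    posture: Posture
    baseline: tuple  # (3,) orientation offset, device units
    amplitude: float = 0.0  # oscillation amplitude (0 for static poses)
    frequency_hz: float = 0.0
    osc_axes: tuple = (1.0, 0.0, 1.0)  # per-axis oscillation weights
    noise_sigma: float = DEFAULT_NOISE_SIGMA

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.frequency_hz >= RATE_HZ / 2:
            raise ValueError(f"oscillation frequency must stay below Nyquist ({RATE_HZ / 2} Hz)")


# Baselines are chosen so that within each sensor every class pair differs by
# >= 0.2 on some axis — more than 4 default noise sigmas — so the 12
# statistical features separate the classes by construction.
DEFAULT_TEMPLATES = {
    Posture.UP: SignalTemplate(Posture.UP, (0.0, 0.0, 1.0)),
    Posture.DOWN: SignalTemplate(Posture.DOWN, (0.9, 0.0, 0.45)),
    Posture.BARK: SignalTemplate(
        Posture.BARK, (0.3, 0.6, 0.95), amplitude=0.5, frequency_hz=4.0
    ),
    Posture.LIE: SignalTemplate(Posture.LIE, (0.0, 0.95, 0.25)),
    Posture.SIT: SignalTemplate(Posture.SIT, (0.4, 0.0, 0.9)),
    Posture.STAND: SignalTemplate(Posture.STAND, (0.0, 0.0, 1.0)),
    Posture.WALK: SignalTemplate(
        Posture.WALK, (0.2, 0.25, 0.95), amplitude=0.4, frequency_hz=2.0
    ),
    Posture.DIG: SignalTemplate(
        Posture.DIG, (0.5, 0.3, 0.8), amplitude=0.7, frequency_hz=5.0
    ),
    Posture.JUMP: SignalTemplate(
        Posture.JUMP, (0.1, 0.5, 0.85), amplitude=1.2, frequency_hz=1.2
    ),
}


def _sensor_of(posture: Posture) -> Sensor:
    from .events import HEAD_POSTURES

    return Sensor.HEAD if posture in HEAD_POSTURES else Sensor.BODY


def _synthesize(
    posture: Posture,
    seconds: float,
    rng: np.random.Generator,
    start_t: float = 0.0,
    start_frame: int = 0,
    noise_sigma: "float | None" = None,
) -> pd.DataFrame:
    template = DEFAULT_TEMPLATES[Posture(posture)]
    sigma = template.noise_sigma if noise_sigma is None else noise_sigma
    n = int(round(seconds * RATE_HZ))
    t = start_t + np.arange(n) / RATE_HZ
    base = np.asarray(template.baseline, dtype=float)
    values = np.tile(base, (n, 1))
    if template.amplitude > 0:
        osc = template.amplitude * np.sin(2 * math.pi * template.frequency_hz * t)
        values = values + osc[:, None] * np.asarray(template.osc_axes, dtype=float)
    if sigma > 0:
        values = values + rng.normal(0.0, sigma, size=values.shape)
    return pd.DataFrame(
        {
            "sensor_id": _sensor_of(posture).value,
            "frame_number": start_frame + np.arange(n),
            "timestamp": t,
            "ax": values[:, 0],
            "ay": values[:, 1],
            "az": values[:, 2],
        },
        columns=COLUMNS,
    )


def generate_posture_signal(
    posture: Posture, seconds: float, seed: int, noise_sigma: "float | None" = None
) -> pd.DataFrame:
    """Generate a 50 Hz six-column log of one posture held for ``seconds``."""
    if seconds <= 0:
        raise ValueError("seconds must be positive")
    if Posture(posture) not in DEFAULT_TEMPLATES:
        raise ValueError(f"unknown posture class {posture!r}")
    rng = np.random.default_rng(seed)
    return _synthesize(posture, seconds, rng, noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# Scenario scripting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One scripted stretch of behavior (atomic- or complex-level label)."""

    label: "AtomicBehavior | ComplexBehavior"
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        try:
            object.__setattr__(self, "label", AtomicBehavior(self.label))
        except ValueError:
            object.__setattr__(self, "label", ComplexBehavior(self.label))
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.start_s < 0:
            raise ValueError("segment start must be non-negative")


@dataclass(frozen=True)
class ScenarioScript:
    """A timeline of behavior segments for one subject.

    Gaps between segments are filled with quiet lying.  Segments must be
    time-ordered and non-overlapping, and start/durations are whole seconds
    (labels have a 1-s granularity).
    """

    subject_id: str
    segments: tuple
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        object.__setattr__(self, "segments", segments)
        end = 0.0
        for seg in segments:
            if seg.start_s < end:
                raise ValueError(
                    f"segment {seg.label.value!r} at {seg.start_s} overlaps the previous one"
                )
            end = seg.start_s + seg.duration_s
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def duration_s(self) -> float:
        if not self.segments:
            return 0.0
        last = self.segments[-1]
        return last.start_s + last.duration_s


@dataclass(frozen=True)
class GroundTruth:
    """Three-level truth for one scripted scenario."""

    subject_id: str
    l1_head: tuple  # Posture per second
    l1_body: tuple
    l2: EventChannel
    l3: EventChannel


# Per-second (head posture, body posture) expansion of each behavior label.
# ``k`` is the second index within the segment.
def _expand_second(label, k: int):
    if isinstance(label, AtomicBehavior):
        return {
            AtomicBehavior.WALKING: (Posture.UP, Posture.WALK),
            AtomicBehavior.LYING: (Posture.UP, Posture.LIE),
            AtomicBehavior.SITTING: (Posture.UP, Posture.SIT),
            AtomicBehavior.STANDING: (Posture.UP, Posture.STAND),
            AtomicBehavior.DIGGING: (Posture.DOWN, Posture.DIG),
            AtomicBehavior.ESCAPING: (Posture.UP, Posture.JUMP),
            AtomicBehavior.BARKING: (Posture.BARK, Posture.STAND),
            # body alternates walk/stand while the head stays down
            AtomicBehavior.SNIFFING: (
                Posture.DOWN,
                Posture.WALK if k % 2 == 0 else Posture.STAND,
            ),
        }[label]
    # complex behaviors: high-frequency alternation of their atomic components
    if label is ComplexBehavior.DESTRUCTIVE:
        # two seconds of jumping, two of digging, repeated
        return (
            (Posture.UP, Posture.JUMP) if k % 4 < 2 else (Posture.DOWN, Posture.DIG)
        )
    if label is ComplexBehavior.EXPLORATORY:
        # walking with intermittent head-down sniffing
        return (Posture.UP if k % 4 < 2 else Posture.DOWN, Posture.WALK)
    if label is ComplexBehavior.VOCALIZATION:
        return (Posture.BARK, Posture.STAND)
    raise ValueError(f"unknown behavior label {label!r}")


_FILL = (Posture.UP, Posture.LIE)  # quiet lying between segments


def script_labels(script: ScenarioScript):
    """Per-second (head, body) posture labels implied by the script."""
    total = int(math.ceil(script.duration_s))
    head = [_FILL[0]] * total
    body = [_FILL[1]] * total
    for seg in script.segments:
        start = int(round(seg.start_s))
        for k in range(int(round(seg.duration_s))):
            h, b = _expand_second(seg.label, k)
            head[start + k] = h
            body[start + k] = b
    return tuple(head), tuple(body)


def labels_to_channel(
    subject_id: str, head_labels, body_labels
) -> EventChannel:
    """Build an oracle L1 channel (1 Hz, both sensors) from per-second labels."""
    channel = EventChannel(level=Level.L1)
    for t, p in enumerate(body_labels):
        channel.publish(PostureEvent(subject_id, Sensor.BODY, Posture(p), float(t)))
    for t, p in enumerate(head_labels):
        channel.publish(PostureEvent(subject_id, Sensor.HEAD, Posture(p), float(t)))
    return channel


def script_to_streams(
    script: ScenarioScript,
    rule_set: "RuleSet | None" = None,
    fuzzy_engine: "FuzzyEngine | None" = None,
):
    """Expand a script into raw head/body logs plus three-level ground truth.

    Returns ``(head_log, body_log, GroundTruth)``.  The L2/L3 truth is
    derived by applying the default rule set and fuzzy engine to the
    intended per-second posture labels.
    """
    if not script.segments:
        empty = pd.DataFrame(columns=COLUMNS)
        return empty, empty, GroundTruth(
            subject_id=script.subject_id,
            l1_head=(),
            l1_body=(),
            l2=EventChannel(level=Level.L2),
            l3=EventChannel(level=Level.L3),
        )
    head_labels, body_labels = script_labels(script)
    rng = np.random.default_rng(script.seed)
    head_parts, body_parts = [], []
    for t, (h, b) in enumerate(zip(head_labels, body_labels)):
        head_parts.append(
            _synthesize(h, 1.0, rng, start_t=float(t), start_frame=t * RATE_HZ,
                        noise_sigma=script.noise_sigma)
        )
        body_parts.append(
            _synthesize(b, 1.0, rng, start_t=float(t), start_frame=t * RATE_HZ,
                        noise_sigma=script.noise_sigma)
        )
    head_log = pd.concat(head_parts, ignore_index=True)
    body_log = pd.concat(body_parts, ignore_index=True)

    l1 = labels_to_channel(script.subject_id, head_labels, body_labels)
    l2, l3 = run_hierarchy(l1, rule_set, fuzzy_engine)
    truth = GroundTruth(
        subject_id=script.subject_id,
        l1_head=head_labels,
        l1_body=body_labels,
        l2=l2,
        l3=l3,
    )
    return head_log, body_log, truth


# ---------------------------------------------------------------------------
# Window-slicing augmentation
# ---------------------------------------------------------------------------

def window_slice_augment(samples, width: int = 100, overlap: float = 0.5):
    """Overlapping-slice augmentation of a sample sequence.

    Slices of ``width`` samples are taken at stride ``width * (1 - overlap)``;
    a sequence shorter than ``width`` yields no slices.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    stride = int(round(width * (1 - overlap)))
    if stride < 1:
        raise ValueError("width and overlap give a zero stride")
    arr = np.asarray(samples)
    n = arr.shape[0]
    if n < width:
        return []
    count = (n - width) // stride + 1
    return [arr[k * stride : k * stride + width] for k in range(count)]


# ---------------------------------------------------------------------------
# Training-set synthesis and scenario presets
# ---------------------------------------------------------------------------

def make_training_set(
    sensor: Sensor,
    windows_per_class: int = 100,
    seed: int = 0,
    noise_sigma: "float | None" = None,
):
    """Labeled, normalized one-second windows for classifier training.

    Generates ``windows_per_class`` seconds of signal per posture class of
    the sensor, fits min-max statistics over the combined recording (so the
    calibration sees every class), and returns ``(X, labels, stats)`` with
    ``X`` of shape ``(n, 50, 3)``.
    """
    from .posture import classes_for_sensor
    from .preprocessing import fit_stats, normalize, segment, to_tensor

    classes = classes_for_sensor(sensor)
    rng = np.random.default_rng(seed)
    logs = []
    labels = []
    frame = 0
    t0 = 0.0
    for posture in classes:
        log = _synthesize(
            posture, float(windows_per_class), rng,
            start_t=t0, start_frame=frame, noise_sigma=noise_sigma,
        )
        logs.append(log)
        labels.extend([posture] * windows_per_class)
        frame += len(log)
        t0 += float(windows_per_class)
    recording = pd.concat(logs, ignore_index=True)
    stats = fit_stats(recording)
    windows, _ = segment(recording)
    X = to_tensor([normalize(w, stats) for w in windows])
    return X, labels, stats


def preset_script(name: str, subject_id: str = "dog-0", seed: int = 0,
                  noise_sigma: float = DEFAULT_NOISE_SIGMA) -> ScenarioScript:
    """Built-in scenario scripts.

    ``normal_day``: calm 150-s routine (lying, sitting, walking, standing,
    brief sniffing) — no symptomatic episode.
    ``sa_episode``: 150-s separation-anxiety episode with sustained
    destructive, exploratory, and vocalization stretches.
    """
    A, C = AtomicBehavior, ComplexBehavior
    if name == "normal_day":
        segments = (
            Segment(A.LYING, 0, 30),
            Segment(A.WALKING, 30, 15),
            Segment(A.SNIFFING, 45, 10),
            Segment(A.SITTING, 55, 30),
            Segment(A.STANDING, 85, 20),
            Segment(A.WALKING, 105, 10),
            Segment(A.LYING, 115, 35),
        )
    elif name == "sa_episode":
        segments = (
            Segment(A.WALKING, 0, 10),
            Segment(C.DESTRUCTIVE, 10, 30),
            Segment(C.VOCALIZATION, 40, 30),
            Segment(C.EXPLORATORY, 70, 45),
            Segment(C.DESTRUCTIVE, 115, 20),
            Segment(A.LYING, 135, 15),
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose normal_day or sa_episode")
    return ScenarioScript(
        subject_id=subject_id, segments=segments, noise_sigma=noise_sigma, seed=seed
    )
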