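import pytest

from caniscope.events import EventChannel, Level, Posture, PostureEvent, Sensor


@pytest.fixture
def l1_channel():
    """Empty Level-1 channel."""
    return EventChannel(level=Level.L1)


def body_event(posture, t, subject="dog-0"):
    return PostureEvent(subject, Sensor.BODY, Posture(posture), float(t))


def head_event(posture, t, subject="dog-0"):
    return PostureEvent(subject, Sensor.HEAD, Posture(posture), float(t))


@pytest.fixture
def make_body_event():
    return body_event


@pytest.fixture
def make_head_event():
    return head_event
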