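"""CEP engine: repeat/follow matching, windowed scanning with consumption,
coverage fractions, and the full hierarchy."""

import math

import numpy as np
import pytest

from caniscope.cep import (
    CepConfig,
    PatternRule,
    RuleKind,
    RuleSet,
    coverage_fraction,
    default_rule_set,
    detect_complex,
    match_c1,
    match_c2,
    rule_set_from_json,
    rule_set_to_json,
    run_hierarchy,
    scan_atomic,
)
from caniscope.events import (
    AtomicBehavior,
    AtomicBehaviorEvent,
    ComplexBehavior,
    EventChannel,
    Level,
    Posture,
    PostureEvent,
    Sensor,
    SymptomState,
)

from conftest import body_event, head_event


def rule_for(output):
    rules = default_rule_set()
    for r in rules.atomic:
        if r.output is AtomicBehavior(output):
            return r
    raise KeyError(output)


class TestMatchC1:
    def test_repeated_dig_emits_digging(self):
        ev = match_c1([body_event("Dig", 0), body_event("Dig", 1)], rule_for("Digging"))
        assert ev is not None
        assert (ev.behavior, ev.ts, ev.te) == (AtomicBehavior.DIGGING, 0.0, 2.0)

    def test_posture_change_blocks_match(self):
        assert match_c1(
            [body_event("Dig", 0), body_event("Walk", 1)], rule_for("Digging")
        ) is None

    def test_repeated_bark_emits_barking(self):
        ev = match_c1([head_event("Bark", 0), head_event("Bark", 1)], rule_for("Barking"))
        assert (ev.behavior, ev.ts, ev.te) == (AtomicBehavior.BARKING, 0.0, 2.0)

    def test_other_sensor_does_not_interrupt(self):
        view = [body_event("Walk", 0), head_event("Down", 0.5), body_event("Walk", 1)]
        ev = match_c1(view, rule_for("Walking"))
        assert ev is not None and ev.ts == 0.0


class TestMatchC2:
    def test_walk_then_head_down_is_sniffing(self):
        ev = match_c2(
            [body_event("Walk", 0), head_event("Down", 1)], rule_for("Sniffing")
        )
        assert (ev.behavior, ev.ts, ev.te) == (AtomicBehavior.SNIFFING, 0.0, 2.0)

    def test_stand_also_accepted_as_first(self):
        ev = match_c2(
            [body_event("Stand", 0), head_event("Down", 1)], rule_for("Sniffing")
        )
        assert ev is not None and ev.ts == 0.0

    def test_order_violation_blocks_match(self):
        assert match_c2(
            [head_event("Down", 0), body_event("Walk", 1)], rule_for("Sniffing")
        ) is None

    def test_simultaneous_not_followed(self):
        assert match_c2(
            [body_event("Walk", 1), head_event("Down", 1)], rule_for("Sniffing")
        ) is None


def make_l1(*events):
    channel = EventChannel(level=Level.L1)
    for ev in events:
        channel.publish(ev)
    return channel


class TestScanAtomic:
    def test_four_seconds_of_walk_yield_two_walking_events(self):
        channel = make_l1(*(body_event("Walk", t) for t in range(4)))
        l2 = scan_atomic(channel)
        spans = [(e.behavior, e.ts, e.te) for e in l2]
        assert spans == [
            (AtomicBehavior.WALKING, 0.0, 2.0),
            (AtomicBehavior.WALKING, 2.0, 4.0),
        ]

    def test_empty_input_empty_output(self):
        assert len(scan_atomic(make_l1())) == 0

    def test_alternation_never_matches(self):
        events = [
            body_event("Walk" if t % 2 == 0 else "Sit", t) for t in range(10)
        ]
        assert len(scan_atomic(make_l1(*events))) == 0

    def test_rejects_non_l1_channel(self):
        with pytest.raises(ValueError, match="L1"):
            scan_atomic(EventChannel(level=Level.L2))

    def test_subjects_processed_independently(self):
        events = [body_event("Dig", t, subject=s) for s in ("a", "b") for t in (0, 1)]
        l2 = scan_atomic(make_l1(*events))
        assert sorted(ev.subject_id for ev in l2) == ["a", "b"]


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence
# ---------------------------------------------------------------------------

def brute_force_scan(events, rules):
    """Plain nested-loop re-implementation of the atomic EPN semantics."""
    if not events:
        return []
    out = []
    used = {r.output: [False] * len(events) for r in rules}
    start = float(math.floor(events[0].t))
    while start <= events[-1].t:
        in_window = [
            k for k, ev in enumerate(events) if start <= ev.t < start + 2.0
        ]
        for rule in rules:
            visible = [k for k in in_window if not used[rule.output][k]]
            if rule.kind is RuleKind.REPEAT_C1:
                sensor = Sensor.HEAD if rule.posture.value in ("Up", "Down", "Bark") else Sensor.BODY
                same_sensor = [k for k in visible if events[k].sensor_id is sensor]
                run = []
                best = None
                for k in same_sensor:
                    if events[k].posture is rule.posture:
                        run.append(k)
                    else:
                        if len(run) >= 2:
                            best = list(run)
                            break
                        run = []
                if best is None and len(run) >= 2:
                    best = run
                if best:
                    first = events[best[0]]
                    out.append(
                        AtomicBehaviorEvent(first.subject_id, rule.output,
                                            first.t, first.t + 2.0)
                    )
                    for k in best:
                        used[rule.output][k] = True
            else:  # follow
                found = None
                for k in visible:
                    if events[k].posture in rule.first:
                        for j in visible:
                            if (
                                events[j].sensor_id is Sensor.HEAD
                                and events[j].posture is rule.second
                                and events[j].t > events[k].t
                            ):
                                found = (k, j)
                                break
                    if found:
                        break
                if found:
                    k, j = found
                    out.append(
                        AtomicBehaviorEvent(events[k].subject_id, rule.output,
                                            events[k].t, events[k].t + 2.0)
                    )
                    used[rule.output][k] = True
                    used[rule.output][j] = True
        start += 1.0
    return out


def random_stream(rng, max_events=60):
    head = [Posture.UP, Posture.DOWN, Posture.BARK]
    body = [Posture.WALK, Posture.LIE, Posture.SIT, Posture.STAND, Posture.DIG, Posture.JUMP]
    n_seconds = int(rng.integers(1, max_events // 2 + 1))
    channel = EventChannel(level=Level.L1)
    for t in range(n_seconds):
        if rng.random() < 0.9:
            channel.publish(
                PostureEvent("d", Sensor.BODY, body[rng.integers(len(body))], float(t))
            )
        if rng.random() < 0.9:
            channel.publish(
                PostureEvent("d", Sensor.HEAD, head[rng.integers(len(head))], float(t))
            )
    return channel


class TestOracleEquivalence:
    def test_scan_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(42)
        rules = [r for r in default_rule_set().atomic]
        for _ in range(200):
            channel = random_stream(rng)
            expected = sorted(
                brute_force_scan(list(channel), rules), key=lambda e: (e.ts, e.behavior.value)
            )
            got = sorted(
                scan_atomic(channel), key=lambda e: (e.ts, e.behavior.value)
            )
            assert got == expected


class TestCoverageFraction:
    def atomic(self, behavior, ts, te):
        return AtomicBehaviorEvent("d", AtomicBehavior(behavior), ts, te)

    def test_no_events_zero(self):
        obs = coverage_fraction([], {AtomicBehavior.WALKING}, 0.0)
        assert obs.f == 0.0

    def test_full_window_one(self):
        events = [self.atomic("Walking", 0, 15)]
        assert coverage_fraction(events, {AtomicBehavior.WALKING}, 0.0).f == 1.0

    def test_disjoint_intervals_sum(self):
        events = [self.atomic("Walking", 0, 3), self.atomic("Sniffing", 5, 6.5)]
        obs = coverage_fraction(
            events, {AtomicBehavior.WALKING, AtomicBehavior.SNIFFING}, 0.0
        )
        assert obs.f == pytest.approx(4.5 / 15)

    def test_overlap_counted_once(self):
        events = [self.atomic("Walking", 0, 4), self.atomic("Sniffing", 2, 6)]
        obs = coverage_fraction(
            events, {AtomicBehavior.WALKING, AtomicBehavior.SNIFFING}, 0.0
        )
        assert obs.f == pytest.approx(6 / 15)

    def test_monotone_under_event_addition(self):
        rng = np.random.default_rng(3)
        events = []
        last = 0.0
        for _ in range(20):
            ts = rng.uniform(0, 14)
            events.append(self.atomic("Walking", ts, ts + rng.uniform(0.5, 3)))
            f = coverage_fraction(events, {AtomicBehavior.WALKING}, 0.0).f
            assert f >= last - 1e-12
            last = f

    def test_invariant_to_splitting_intervals(self):
        whole = [self.atomic("Walking", 2, 8)]
        split = [self.atomic("Walking", 2, 5), self.atomic("Walking", 5, 8)]
        f1 = coverage_fraction(whole, {AtomicBehavior.WALKING}, 0.0).f
        f2 = coverage_fraction(split, {AtomicBehavior.WALKING}, 0.0).f
        assert f1 == pytest.approx(f2)

    def test_count_mode(self):
        events = [self.atomic("Walking", 0, 2), self.atomic("Walking", 2, 4)]
        obs = coverage_fraction(events, {AtomicBehavior.WALKING}, 0.0, mode="count")
        assert obs.f == pytest.approx(2 / 15)


class TestDetectComplex:
    def test_all_quiet_emits_three_normal(self):
        l2 = EventChannel(level=Level.L2)
        l2.publish(AtomicBehaviorEvent("d", AtomicBehavior.LYING, 0, 2))
        l3 = detect_complex(l2)
        assert len(l3) == 3
        assert all(ev.d is SymptomState.NORMAL for ev in l3)
        assert {ev.behavior for ev in l3} == set(ComplexBehavior)

    def test_full_walking_window_is_abnormal_exploratory(self):
        l2 = EventChannel(level=Level.L2)
        for ts in range(0, 14, 2):
            l2.publish(AtomicBehaviorEvent("d", AtomicBehavior.WALKING, ts, ts + 2))
        l3 = detect_complex(l2)
        exploratory = [ev for ev in l3 if ev.behavior is ComplexBehavior.EXPLORATORY]
        assert len(exploratory) == 1
        assert exploratory[0].d is SymptomState.ABNORMAL

    def test_empty_l2_empty_l3(self):
        assert len(detect_complex(EventChannel(level=Level.L2))) == 0


class TestRunHierarchy:
    def test_empty_input(self):
        l2, l3 = run_hierarchy(EventChannel(level=Level.L1))
        assert len(l2) == 0 and len(l3) == 0

    def test_lying_only_never_abnormal(self):
        channel = make_l1(*(body_event("Lie", t) for t in range(120)))
        l2, l3 = run_hierarchy(channel)
        assert all(ev.behavior is AtomicBehavior.LYING for ev in l2)
        assert len(l3) > 0
        assert all(ev.d is SymptomState.NORMAL for ev in l3)

    def test_deterministic(self):
        events = [body_event("Dig", t) for t in range(30)] + [
            head_event("Bark", t) for t in range(30)
        ]
        a = run_hierarchy(make_l1(*events))
        b = run_hierarchy(make_l1(*events))
        assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])


class TestRuleSet:
    def test_every_atomic_class_produced(self):
        produced = {r.output for r in default_rule_set().atomic}
        assert produced == set(AtomicBehavior)

    def test_complex_operands_must_be_produced(self):
        with pytest.raises(ValueError, match="produced by no rule"):
            RuleSet(
                atomic=(
                    PatternRule(
                        kind=RuleKind.REPEAT_C1,
                        output=AtomicBehavior.WALKING,
                        window_s=2.0,
                        posture=Posture.WALK,
                    ),
                ),
                complex=(
                    PatternRule(
                        kind=RuleKind.AGGREGATE_A,
                        output=ComplexBehavior.VOCALIZATION,
                        window_s=15.0,
                        operands=frozenset({AtomicBehavior.BARKING}),
                    ),
                ),
            )

    def test_json_round_trip(self, tmp_path):
        rules = default_rule_set()
        path = tmp_path / "rules.json"
        rule_set_to_json(rules, path)
        assert rule_set_from_json(path) == rules

    def test_and_or_operands_behave_as_set_membership(self):
        """Or-composition of rule operands: matching either operand class
        contributes; de Morgan-style complement check on a toy window."""
        rule = next(
            r for r in default_rule_set().complex
            if r.output is ComplexBehavior.DESTRUCTIVE
        )
        escaping = AtomicBehaviorEvent("d", AtomicBehavior.ESCAPING, 0, 2)
        digging = AtomicBehaviorEvent("d", AtomicBehavior.DIGGING, 5, 7)
        lying = AtomicBehaviorEvent("d", AtomicBehavior.LYING, 8, 10)
        f_union = coverage_fraction([escaping, digging, lying], rule.operands, 0.0).f
        f_a = coverage_fraction([escaping], {AtomicBehavior.ESCAPING}, 0.0).f
        f_b = coverage_fraction([digging], {AtomicBehavior.DIGGING}, 0.0).f
        # disjoint intervals: union coverage = sum of parts; non-operand ignored
        assert f_union == pytest.approx(f_a + f_b)
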