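"""Precision/recall/F1 metrics and event matching against ground truth.

Per class: P = TP / (TP + FP), R = TP / (TP + FN), F1 = 2PR / (P + R), with
zero-division cases returning 0.  The reported average is the unweighted
macro mean over classes.

Matching predicted events to truth:

* Level 1 — per-second label comparison, keyed by (sensor, second).
* Level 2/3 — a predicted event is a true positive iff a not-yet-matched
  truth event of the same class (and, for Level 3, the same symptom state)
  overlaps it by more than half of the truth event's duration; each truth
  event is matched at most once.  The overlap threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import Level

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "precision_recall_f1",
    "confusion_from_labels",
    "match_events",
]


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN counts."""

    counts: dict = field(default_factory=dict)  # class -> [tp, fp, fn]

    def __post_init__(self) -> None:
        for cls, (tp, fp, fn) in self.counts.items():
            if min(tp, fp, fn) < 0:
                raise ValueError(f"negative count for class {cls!r}")

    def add(self, cls, tp: int = 0, fp: int = 0, fn: int = 0) -> None:
        if min(tp, fp, fn) < 0:
            raise ValueError("counts must be non-negative")
        entry = self.counts.setdefault(cls, [0, 0, 0])
        entry[0] += tp
        entry[1] += fp
        entry[2] += fn


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro-averaged precision/recall/F1."""

    per_class: dict  # class -> {"precision", "recall", "f1", "support"}
    macro: dict  # {"precision", "recall", "f1"}
    level: "Level | None" = None

    def to_dict(self) -> dict:
        out = {"per_class": self.per_class, "average": self.macro}
        if self.level is not None:
            out["level"] = Level(self.level).value
        return out

    def render_table(self) -> str:
        """Plain-text table: one row per class plus the macro average."""
        rows = [("Category", "Num.", "Precision", "Recall", "F1-Score")]
        for cls, m in self.per_class.items():
            rows.append(
                (str(cls), str(m["support"]),
                 f"{m['precision']:.3f}", f"{m['recall']:.3f}", f"{m['f1']:.3f}")
            )
        rows.append(
            ("Average", "", f"{self.macro['precision']:.3f}",
             f"{self.macro['recall']:.3f}", f"{self.macro['f1']:.3f}")
        )
        widths = [max(len(r[i]) for r in rows) for i in range(5)]
        return "\n".join(
            "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
        )


def _prf(tp: int, fp: int, fn: int):
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def precision_recall_f1(
    counts: ConfusionCounts, level: "Level | None" = None
) -> MetricsReport:
    """Compute per-class and macro precision/recall/F1 from confusion counts."""
    per_class = {}
    for cls, (tp, fp, fn) in counts.counts.items():
        if min(tp, fp, fn) < 0:
            raise ValueError(f"negative count for class {cls!r}")
        p, r, f1 = _prf(tp, fp, fn)
        per_class[cls] = {
            "precision": p, "recall": r, "f1": f1, "support": tp + fn,
        }
    n = len(per_class)
    macro = {
        key: (sum(m[key] for m in per_class.values()) / n if n else 0.0)
        for key in ("precision", "recall", "f1")
    }
    return MetricsReport(per_class=per_class, macro=macro, level=level)


def confusion_from_labels(truth, predicted, classes=None) -> ConfusionCounts:
    """Element-wise confusion counts for aligned label sequences."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted label sequences differ in length")
    counts = ConfusionCounts()
    for cls in classes or ():
        counts.counts.setdefault(cls, [0, 0, 0])
    for t, p in zip(truth, predicted):
        if t == p:
            counts.add(t, tp=1)
        else:
            counts.add(p, fp=1)
            counts.add(t, fn=1)
    return counts


def _l3_key(event):
    return (event.behavior, event.d)


def _l2_key(event):
    return (event.behavior,)


def match_events(
    truth, predicted, level: Level, overlap_threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts from truth/predicted event sequences at one level."""
    level = Level(level)
    counts = ConfusionCounts()
    if level is Level.L1:
        truth_map = {(ev.sensor_id, round(ev.t)): ev.posture for ev in truth}
        pred_map = {(ev.sensor_id, round(ev.t)): ev.posture for ev in predicted}
        for key in sorted(set(truth_map) | set(pred_map), key=lambda k: (k[0].value, k[1])):
            t = truth_map.get(key)
            p = pred_map.get(key)
            if t is not None and p is not None:
                if t == p:
                    counts.add(t, tp=1)
                else:
                    counts.add(p, fp=1)
                    counts.add(t, fn=1)
            elif t is not None:
                counts.add(t, fn=1)
            else:
                counts.add(p, fp=1)
        return counts

    key_of = _l3_key if level is Level.L3 else _l2_key
    truth_events = sorted(truth, key=lambda ev: ev.ts)
    matched = [False] * len(truth_events)
    for pred in sorted(predicted, key=lambda ev: ev.ts):
        best_i, best_overlap = None, 0.0
        for i, tr in enumerate(truth_events):
            if matched[i] or key_of(tr) != key_of(pred):
                continue
            if getattr(tr, "subject_id", None) != getattr(pred, "subject_id", None):
                continue
            overlap = min(tr.te, pred.te) - max(tr.ts, pred.ts)
            if overlap > best_overlap:
                best_i, best_overlap = i, overlap
        cls = key_of(pred)[0].value if level is Level.L2 else (
            f"{pred.behavior.value}/{pred.d.value}"
        )
        if (
            best_i is not None
            and best_overlap
            > overlap_threshold * (truth_events[best_i].te - truth_events[best_i].ts)
        ):
            matched[best_i] = True
            counts.add(cls, tp=1)
        else:
            counts.add(cls, fp=1)
    for i, tr in enumerate(truth_events):
        if not matched[i]:
            cls = key_of(tr)[0].value if level is Level.L2 else (
                f"{tr.behavior.value}/{tr.d.value}"
            )
            counts.add(cls, fn=1)
    return counts
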