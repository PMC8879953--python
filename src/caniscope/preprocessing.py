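"""Raw sensor-log preprocessing: segmentation, min-max normalization, shaping.

The input is the wearable's six-column log — sensor ID, frame number,
timestamp (s), and x/y/z acceleration — sampled nominally at 50 Hz.  The
pipeline cuts the stream into consecutive non-overlapping one-second windows
of exactly 50 samples, rescales each axis to [0, 1] with per-recording
min-max statistics (inter-individual scale differences make absolute
acceleration ranges incomparable across dogs), and stacks the windows into a
``(samples, 50, 3)`` batch for the posture classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .events import Sensor

__all__ = [
    "COLUMNS",
    "RATE_HZ",
    "WINDOW_S",
    "TIMESTEPS",
    "NormalizationStats",
    "read_sensor_log",
    "write_sensor_log",
    "segment",
    "fit_stats",
    "normalize",
    "to_tensor",
    "preprocess_log",
]

COLUMNS = ["sensor_id", "frame_number", "timestamp", "ax", "ay", "az"]
RATE_HZ = 50
WINDOW_S = 1.0
TIMESTEPS = 50

#: Tolerated relative disagreement between frame count and time span.
_RATE_TOLERANCE = 0.05

#: Default calibration prefix (s) for live-stream normalization statistics.
CALIBRATION_PREFIX_S = 60.0


@dataclass(frozen=True)
class NormalizationStats:
    """Per-sensor, per-axis min/max over a calibration span."""

    sensor_id: Sensor
    minimum: np.ndarray  # shape (3,)
    maximum: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        mn = np.asarray(self.minimum, dtype=float).reshape(3)
        mx = np.asarray(self.maximum, dtype=float).reshape(3)
        object.__setattr__(self, "minimum", mn)
        object.__setattr__(self, "maximum", mx)
        if np.any(mx < mn):
            raise ValueError("normalization stats require max >= min per axis")


def read_sensor_log(path) -> pd.DataFrame:
    """Read a six-column sensor log CSV (header optional, fixed column order)."""
    path = Path(path)
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = False
    try:
        float(first.iloc[0, 1])
    except (TypeError, ValueError):
        has_header = True
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise ValueError(f"expected 6 columns, got {df.shape[1]} in {path}")
    df.columns = COLUMNS
    df["frame_number"] = df["frame_number"].astype(int)
    for col in ("timestamp", "ax", "ay", "az"):
        df[col] = df[col].astype(float)
    return df


def write_sensor_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, header=True, columns=COLUMNS)


def _check_sorted_single_sensor(samples: pd.DataFrame) -> None:
    if samples.empty:
        return
    if samples["sensor_id"].nunique() > 1:
        raise ValueError("segment expects samples from a single sensor")
    frames = samples["frame_number"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        raise ValueError("samples must be sorted by strictly increasing frame_number")


def _check_rate(samples: pd.DataFrame, rate_hz: float) -> None:
    t = samples["timestamp"].to_numpy()
    span = t[-1] - t[0]
    if span <= 0:
        return
    expected = span * rate_hz
    if abs((len(samples) - 1) - expected) / expected > _RATE_TOLERANCE:
        raise ValueError(
            f"frame count ({len(samples)}) and time span ({span:.2f} s) disagree "
            f"by more than {_RATE_TOLERANCE:.0%} at {rate_hz} Hz; "
            "irregular streams are not resampled"
        )


def segment(
    samples: pd.DataFrame,
    window_s: float = WINDOW_S,
    rate_hz: int = RATE_HZ,
):
    """Cut one sensor's log into consecutive non-overlapping windows.

    Returns ``(windows, start_times)`` where ``windows`` has shape
    ``(k, rate_hz * window_s, 3)``; the trailing partial window is dropped.
    """
    _check_sorted_single_sensor(samples)
    width = int(round(rate_hz * window_s))
    if width <= 0:
        raise ValueError("window_s and rate_hz must be positive")
    n = len(samples)
    k = n // width
    if n > 1:
        _check_rate(samples, rate_hz)
    values = samples[["ax", "ay", "az"]].to_numpy(dtype=float)
    times = samples["timestamp"].to_numpy(dtype=float)
    windows = values[: k * width].reshape(k, width, 3)
    start_times = times[: k * width : width] if k else np.empty(0)
    return windows, start_times


def fit_stats(samples: pd.DataFrame) -> NormalizationStats:
    """Per-axis min/max over a full recording (or calibration prefix)."""
    if samples.empty:
        raise ValueError("cannot fit normalization stats on an empty recording")
    _check_sorted_single_sensor(samples)
    values = samples[["ax", "ay", "az"]].to_numpy(dtype=float)
    return NormalizationStats(
        sensor_id=Sensor(samples["sensor_id"].iloc[0]),
        minimum=values.min(axis=0),
        maximum=values.max(axis=0),
    )


def normalize(window: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Min-max rescale one raw window to [0, 1].

    Out-of-calibration values are clipped; a degenerate axis (max == min)
    maps to 0.5 everywhere.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValueError(f"expected a (timesteps, 3) window, got {window.shape}")
    span = stats.maximum - stats.minimum
    out = np.empty_like(window)
    for axis in range(3):
        if span[axis] == 0:
            out[:, axis] = 0.5
        else:
            out[:, axis] = (window[:, axis] - stats.minimum[axis]) / span[axis]
    return np.clip(out, 0.0, 1.0)


def to_tensor(windows) -> np.ndarray:
    """Stack normalized windows into a ``(samples, 50, 3)`` batch."""
    windows = list(windows)
    if not windows:
        return np.empty((0, TIMESTEPS, 3))
    arrays = [np.asarray(w, dtype=float) for w in windows]
    shape = arrays[0].shape
    for i, arr in enumerate(arrays):
        if arr.shape != shape:
            raise ValueError(
                f"ragged batch: window 0 has shape {shape}, window {i} has {arr.shape}"
            )
    if shape != (TIMESTEPS, 3):
        raise ValueError(f"windows must have shape ({TIMESTEPS}, 3), got {shape}")
    return np.stack(arrays)


def preprocess_log(
    samples: pd.DataFrame,
    stats: "NormalizationStats | None" = None,
):
    """Full pipeline for one sensor log: segment, normalize, stack.

    Returns ``(tensor, start_times, stats)``.  When ``stats`` is None they
    are fitted on the recording itself.
    """
    if stats is None and not samples.empty:
        stats = fit_stats(samples)
    windows, start_times = segment(samples)
    if len(windows) == 0:
        return np.empty((0, TIMESTEPS, 3)), start_times, stats
    normalized = [normalize(w, stats) for w in windows]
    return to_tensor(normalized), start_times, stats
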