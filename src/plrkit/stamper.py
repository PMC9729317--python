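"""Light-onset timestamping from a camera frame stream, and timed capture of
streamed samples.

Detection follows the two-frame differencing rule used with a forward-facing
scene camera: keep the two most recent frames and report the timestamp of the
first frame whose whole-frame mean intensity exceeds the previous frame's by
more than a threshold.  Only positive steps (onsets) are detected by default;
``absolute=True`` also detects offsets.  Detection runs either synchronously
or in its own thread with a deferred (`Future`) result, so several stampers
can monitor independent streams concurrently.

Timeouts are counted in stream time (frame timestamps), not wall time, so
behaviour is deterministic under test.
"""

from __future__ import annotations

import csv
from concurrent.futures import Future, ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError


@dataclass(frozen=True)
class Frame:
    """One camera frame reduced to its whole-frame mean intensity."""

    timestamp_s: float
    mean_rgb: float

    @classmethod
    def from_pixels(cls, timestamp_s: float, pixels) -> "Frame":
        """Reduce a full pixel array (any shape/channels) to its pooled mean."""
        return cls(timestamp_s, float(np.mean(pixels)))


@dataclass(frozen=True)
class StampResult:
    detected: bool
    timestamp_s: float | None
    frames_seen: int
    threshold: float


def light_stamp(
    stream,
    threshold: float,
    timeout_s: float,
    absolute: bool = False,
) -> StampResult:
    """Detect a light onset in a frame stream by two-frame differencing.

    Returns the timestamp of the first frame whose mean intensity difference
    from the previous frame exceeds ``threshold`` (strictly), or a
    not-detected result once ``timeout_s`` of stream time has elapsed since
    the first frame.
    """
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    if timeout_s <= 0:
        raise DomainError("timeout must be positive")
    prev = None
    t0 = None
    seen = 0
    for frame in stream:
        seen += 1
        if t0 is None:
            t0 = frame.timestamp_s
        elif frame.timestamp_s - t0 > timeout_s:
            return StampResult(False, None, seen, threshold)
        if prev is not None:
            diff = frame.mean_rgb - prev.mean_rgb
            if absolute:
                diff = abs(diff)
            if diff > threshold:
                return StampResult(True, frame.timestamp_s, seen, threshold)
        prev = frame
    return StampResult(False, None, seen, threshold)


def light_stamp_async(stream, threshold: float, timeout_s: float, absolute: bool = False) -> Future:
    """Run :func:`light_stamp` in its own thread; result via ``.result()``."""
    executor = ThreadPoolExecutor(max_workers=1)
    future = executor.submit(light_stamp, stream, threshold, timeout_s, absolute)
    executor.shutdown(wait=False)
    return future


def apply_timestamp_offset(timestamp_s: float, offset_ms: float = 0.0) -> float:
    """Correct a frame timestamp for a fixed camera latency offset.

    On some operating systems scene-camera timestamps lead the eye-camera
    clock by a repeatable amount (around 60 ms on Windows); subtracting the
    measured offset aligns onset-referenced latencies.  Default 0 (no
    correction).
    """
    return timestamp_s - offset_ms / 1000.0


# ---------------------------------------------------------------------------
# timed capture of streamed, topic-keyed records


@dataclass(frozen=True)
class CaptureWindow:
    """Records captured from a stream for a fixed span of stream time."""

    topic_prefix: str
    duration_s: float
    samples: tuple = field(default_factory=tuple)

    def __len__(self):
        return len(self.samples)


def grab(stream, topic_prefix: str, duration_s: float) -> CaptureWindow:
    """Collect records whose topic starts with a prefix.

    The window covers ``duration_s`` of stream time, measured from the first
    record seen (matching or not).  Records are dicts with at least
    ``topic`` and ``timestamp`` keys.
    """
    if duration_s <= 0:
        raise DomainError("duration must be positive")
    t0 = None
    collected = []
    for rec in stream:
        ts = rec["timestamp"]
        if t0 is None:
            t0 = ts
        if ts - t0 > duration_s:
            break
        if rec["topic"].startswith(topic_prefix):
            collected.append(rec)
    return CaptureWindow(topic_prefix, duration_s, tuple(collected))


def grab_async(stream, topic_prefix: str, duration_s: float) -> Future:
    """Run :func:`grab` in its own thread; result via ``.result()``."""
    executor = ThreadPoolExecutor(max_workers=1)
    future = executor.submit(grab, stream, topic_prefix, duration_s)
    executor.shutdown(wait=False)
    return future


def unpack_window(window: CaptureWindow) -> pd.DataFrame:
    """Organise captured records into a timestamp-indexed table.

    Columns are the union of record keys; records missing a key get NaN.
    """
    if len(window) == 0:
        return pd.DataFrame()
    df = pd.DataFrame(list(window.samples))
    return df.set_index("timestamp")


def write_annotations(path, annotations: list[tuple[str, float]]) -> None:
    """Write (label, timestamp_s) annotation rows as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "timestamp"])
        for label, ts in annotations:
            writer.writerow([label, f"{ts:.9g}"])
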