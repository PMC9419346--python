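"""Raw streams and event files → aligned 10-s epoch sequences.

Conventions (all deterministic, all logged):

* 30 → 10 Hz by block mean over 3 consecutive samples (robust to phase,
  mildly anti-aliasing), not naive decimation.
* A second takes the label of the posture event covering its *start*
  instant; an event change exactly on a second boundary hands the second
  to the new event.
* A 10-s epoch is SIT iff >= 6 of its seconds are SIT.
* Trailing partial epochs/windows are dropped, never padded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from chapchild.io_formats import (
    NONSIT,
    SIT,
    UNWORN,
    EpochLabelSeries,
    PostureEventList,
    RawTriaxialStream,
)

log = logging.getLogger(__name__)

#: seconds of sitting (out of 10) required to call an epoch sedentary
SIT_SECONDS_THRESHOLD = 6

WINDOW_SAMPLES = 100  # 10 s at 10 Hz


@dataclass
class EpochWindow:
    """One 10-s window of 10 Hz signal: exactly 100 x 3 g values."""

    index: int
    t_start: datetime
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float32)
        if self.signal.shape != (WINDOW_SAMPLES, 3):
            raise ValueError(f"window must be {WINDOW_SAMPLES} x 3, got {self.signal.shape}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("window contains non-finite values")


@dataclass
class WearMask:
    """Ordered disjoint (start, end) wear intervals."""

    intervals: list[tuple[datetime, datetime]]

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if not s < e:
                raise ValueError("mask interval must satisfy start < end")
        for (s1, e1), (s2, e2) in zip(self.intervals, self.intervals[1:]):
            if s2 < e1:
                raise ValueError("mask intervals must be sorted and disjoint")

    def covers(self, start: datetime, end: datetime) -> bool:
        """True if [start, end] lies inside a single wear interval."""
        return any(s <= start and end <= e for s, e in self.intervals)

    def total_seconds(self) -> float:
        return sum((e - s).total_seconds() for s, e in self.intervals)

    def intersect(self, other: "WearMask") -> "WearMask":
        out = []
        for s1, e1 in self.intervals:
            for s2, e2 in other.intervals:
                s, e = max(s1, s2), min(e1, e2)
                if s < e:
                    out.append((s, e))
        return WearMask(sorted(out))


def downsample_to_10hz(stream: RawTriaxialStream) -> RawTriaxialStream:
    """30 Hz → 10 Hz by per-axis mean over blocks of 3 samples."""
    if not np.isclose(stream.rate_hz, 30.0):
        raise ValueError(f"expected a 30 Hz stream, got {stream.rate_hz:g} Hz")
    n = stream.n_samples
    keep = (n // 3) * 3
    if keep != n:
        log.warning("dropping %d trailing samples not filling a 3-block", n - keep)
    blocks = stream.samples[:keep].reshape(-1, 3, 3)
    return RawTriaxialStream(
        stream.start_time,
        10.0,
        blocks.mean(axis=1),
        device_id=stream.device_id,
    )


def events_to_second_labels(
    events: PostureEventList, span: tuple[datetime, datetime] | None = None
) -> tuple[datetime, np.ndarray]:
    """Label each whole second of ``span`` with the covering event's posture.

    Returns ``(first_second, labels)``. The span defaults to the events'
    full coverage rounded inward to whole seconds; a second belongs to the
    event covering its start instant.
    """
    if span is None:
        start = events.start_time
        if start.microsecond:
            start = (start + timedelta(seconds=1)).replace(microsecond=0)
        end = events.end_time
        end = end.replace(microsecond=0)
    else:
        start, end = span
        if start < events.start_time or end > events.end_time + timedelta(seconds=1e-6):
            raise ValueError("span outside event coverage")
    n_sec = int(math.floor((end - start).total_seconds()))
    if n_sec <= 0:
        return start, np.empty(0, dtype=object)
    offsets = (start - events.start_time).total_seconds() + np.arange(n_sec)
    # boundary seconds go to the NEW event: searchsorted(side='right') - 1
    bounds = np.concatenate([events.starts_s, [events.total_duration_s]])
    idx = np.searchsorted(bounds, offsets + 1e-9, side="right") - 1
    idx = np.clip(idx, 0, len(events) - 1)
    return start, events.labels[idx]


def aggregate_to_epochs(
    second_labels: np.ndarray,
    start_time: datetime,
    epoch_s: int = 10,
    source: str = "activpal",
) -> EpochLabelSeries:
    """Collapse per-second posture labels into epochs.

    SIT iff at least :data:`SIT_SECONDS_THRESHOLD` of ``epoch_s`` seconds
    are SIT, else NONSIT. Trailing seconds not filling an epoch are dropped.
    """
    n = len(second_labels)
    keep = (n // epoch_s) * epoch_s
    if keep != n:
        log.warning("dropping %d trailing seconds not filling an epoch", n - keep)
    if keep == 0:
        return EpochLabelSeries(start_time, epoch_s, np.empty(0, dtype=object), None, source)
    grid = np.asarray(second_labels[:keep], dtype=object).reshape(-1, epoch_s)
    sit_sec = (grid == SIT).sum(axis=1)
    thresh = SIT_SECONDS_THRESHOLD if epoch_s == 10 else int(np.ceil(0.6 * epoch_s))
    labels = np.where(sit_sec >= thresh, SIT, NONSIT).astype(object)
    return EpochLabelSeries(start_time, epoch_s, labels, None, source)


def window_raw(stream: RawTriaxialStream) -> list[EpochWindow]:
    """Cut a 10 Hz stream into consecutive non-overlapping 100-sample windows."""
    if not np.isclose(stream.rate_hz, 10.0):
        raise ValueError(f"expected a 10 Hz stream, got {stream.rate_hz:g} Hz")
    n = stream.n_samples
    if n < WINDOW_SAMPLES:
        raise ValueError(f"stream has {n} samples; one window needs {WINDOW_SAMPLES}")
    n_win = n // WINDOW_SAMPLES
    if n % WINDOW_SAMPLES:
        log.warning("dropping %d trailing samples not filling a window", n % WINDOW_SAMPLES)
    wins = []
    for i in range(n_win):
        t = stream.start_time + timedelta(seconds=10.0 * i)
        wins.append(EpochWindow(i, t, stream.samples[i * 100 : (i + 1) * 100]))
    return wins


def stack_windows(windows: list[EpochWindow]) -> np.ndarray:
    """(n, 100, 3) float32 tensor for the model stage."""
    return np.stack([w.signal for w in windows]) if windows else np.empty((0, 100, 3), np.float32)


def align_and_mask(
    pred: EpochLabelSeries,
    truth: EpochLabelSeries,
    masks: list[WearMask],
) -> tuple[np.ndarray, np.ndarray, list[datetime]]:
    """Pair prediction and truth epochs inside the wear-mask intersection.

    Only epochs whose full span lies in both series' coverage and inside
    every mask survive; returns (pred_labels, truth_labels, epoch_starts)
    index-aligned by timestamp.
    """
    if pred.epoch_s != truth.epoch_s:
        raise ValueError("series must share epoch_s")
    step = timedelta(seconds=pred.epoch_s)
    lo = max(pred.start_time, truth.start_time)
    hi = min(pred.end_time, truth.end_time)
    if lo >= hi:
        raise ValueError("series have no temporal overlap")
    # advance lo to the prediction grid (series must share a grid phase)
    off = (lo - pred.start_time).total_seconds()
    k = math.ceil(off / pred.epoch_s - 1e-9)
    lo = pred.start_time + k * step
    p_lab, t_lab, starts = [], [], []
    t = lo
    while t + step <= hi:
        if all(m.covers(t, t + step) for m in masks):
            ip = round((t - pred.start_time).total_seconds() / pred.epoch_s)
            it = round((t - truth.start_time).total_seconds() / truth.epoch_s)
            if abs((truth.start_time + it * step) - t) > timedelta(seconds=1e-6):
                raise ValueError("series grids are phase-shifted; re-anchor first")
            p_lab.append(pred.labels[ip])
            t_lab.append(truth.labels[it])
            starts.append(t)
        t += step
    return (
        np.array(p_lab, dtype=object),
        np.array(t_lab, dtype=object),
        starts,
    )
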