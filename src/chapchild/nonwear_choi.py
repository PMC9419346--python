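"""Choi non-wear detection on 60-s ActiGraph counts.

A minute is non-wear iff it lies in a run of >= 90 consecutive zero-count
minutes, where a burst of up to 2 consecutive nonzero minutes ("artifactual
movement") is absorbed into the run only when flanked on both sides by
>= 30 consecutive zero-count minutes (the 30-min up/downstream window).
Absorbed spike minutes count toward the 90-min run length. Everything else
is wear.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np

from chapchild.io_formats import CountsStream
from chapchild.preprocess import WearMask


@dataclass(frozen=True)
class ChoiParams:
    min_window_min: int = 90
    spike_tolerance_min: int = 2
    flank_window_min: int = 30

    def __post_init__(self) -> None:
        if min(self.min_window_min, self.spike_tolerance_min, self.flank_window_min) <= 0:
            raise ValueError("all Choi parameters must be positive")
        if self.spike_tolerance_min >= self.min_window_min:
            raise ValueError("spike tolerance must be smaller than the window")


def _runs(values: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs as (start, length, is_zero)."""
    out = []
    i, n = 0, len(values)
    while i < n:
        j = i
        z = values[i] == 0
        while j < n and (values[j] == 0) == z:
            j += 1
        out.append((i, j - i, bool(z)))
        i = j
    return out


def nonwear_minutes(counts: np.ndarray, params: ChoiParams = ChoiParams()) -> np.ndarray:
    """Boolean vector: True where the minute is classified non-wear."""
    counts = np.asarray(counts)
    n = len(counts)
    flag = np.zeros(n, dtype=bool)
    if n == 0:
        return flag
    runs = _runs(counts)
    # a nonzero run is "absorbable" iff short enough and flanked by long zero runs
    ok = np.zeros(n, dtype=bool)
    for k, (start, length, is_zero) in enumerate(runs):
        if is_zero:
            ok[start : start + length] = True
        else:
            left_ok = (
                k > 0 and runs[k - 1][2] and runs[k - 1][1] >= params.flank_window_min
            )
            right_ok = (
                k + 1 < len(runs)
                and runs[k + 1][2]
                and runs[k + 1][1] >= params.flank_window_min
            )
            if length <= params.spike_tolerance_min and left_ok and right_ok:
                ok[start : start + length] = True
    # maximal ok-runs of sufficient length are non-wear
    for start, length, is_ok in _runs((~ok).astype(int)):
        if is_ok and length >= params.min_window_min:
            flag[start : start + length] = True
    return flag


def detect_nonwear(counts: CountsStream, params: ChoiParams = ChoiParams()) -> WearMask:
    """Run Choi on a counts stream; returns the complement as wear intervals."""
    flag = nonwear_minutes(counts.counts_vertical, params)
    intervals = []
    t0 = counts.start_time
    i, n = 0, len(flag)
    while i < n:
        if not flag[i]:
            j = i
            while j < n and not flag[j]:
                j += 1
            intervals.append(
                (t0 + timedelta(minutes=i), t0 + timedelta(minutes=j))
            )
            i = j
        else:
            i += 1
    return WearMask(intervals)
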