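"""Device file dialects and the pipeline's own epoch/summary outputs.

Three input dialects are supported, mirroring what the devices export:

* ActiGraph RAW CSV — 10-line ActiLife-style header, then one row per
  30 Hz triaxial sample in g units (with or without a timestamp column).
* ActiGraph 60-s epoch counts CSV — same header style, one row per minute
  with vertical-axis counts (``Axis1``).
* activPAL events CSV — one row per posture interval (start, duration in
  seconds, activity code 0 = sit/lie, 1 = stand, 2 = step).

All timestamps are timezone-naive local time, matching device behaviour;
DST transitions are out of scope.  Every reader validates its contract and
raises :class:`ParseError` rather than silently repairing gaps or overlaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

SIT = "SIT"
NONSIT = "NONSIT"
UNWORN = "UNWORN"
UPRIGHT = "UPRIGHT"

EPOCH_LABELS = (SIT, NONSIT, UNWORN)
EVENT_LABELS = (SIT, UPRIGHT)

_TS_FMT = "%Y-%m-%d %H:%M:%S"


class ParseError(ValueError):
    """A device file violated its format contract."""


class RateMismatchError(ParseError):
    """Header sampling rate disagrees with the caller's expectation."""


class ContiguityError(ParseError):
    """Event intervals overlap or leave gaps."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RawTriaxialStream:
    """Uniformly sampled triaxial acceleration in g units.

    ``samples`` is an (n, 3) float32 array; ``rate_hz`` is 30 for device
    exports and 10 after downsampling.
    """

    start_time: datetime
    rate_hz: float
    samples: np.ndarray
    device_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("acceleration values must be finite")
        if self.samples.size and np.abs(self.samples).max() >= 16.0:
            raise ValueError("acceleration magnitude must be < 16 g")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.duration_s)


@dataclass
class CountsStream:
    """ActiGraph activity counts at 60-s epochs (vertical axis required)."""

    start_time: datetime
    counts_vertical: np.ndarray
    epoch_s: int = 60
    counts_x2: np.ndarray | None = None
    counts_x3: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.epoch_s != 60:
            raise ValueError(f"counts epoch must be 60 s, got {self.epoch_s}")
        self.counts_vertical = np.asarray(self.counts_vertical, dtype=np.int64)
        if self.counts_vertical.size and self.counts_vertical.min() < 0:
            raise ValueError("counts must be non-negative")
        for name in ("counts_x2", "counts_x3"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.int64)
                if len(v) != len(self.counts_vertical):
                    raise ValueError(f"{name} length mismatch")
                if v.size and v.min() < 0:
                    raise ValueError("counts must be non-negative")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.counts_vertical)


@dataclass
class PostureEventList:
    """Ordered, contiguous posture intervals (SIT / UPRIGHT).

    Contiguity is structural: each event starts where the previous one
    ended, so only the first start time and per-event durations are stored.
    ``provenance`` is "device" or "registered-simulator" for inclinometer
    output obeying the 10-s registration rule, "simulator" for exact
    (pre-registration) truth.
    """

    start_time: datetime
    durations_s: np.ndarray
    labels: np.ndarray
    provenance: str = "device"

    MIN_REGISTERED_S = 10.0

    def __post_init__(self) -> None:
        self.durations_s = np.asarray(self.durations_s, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.durations_s) != len(self.labels):
            raise ValueError("durations and labels length mismatch")
        if self.durations_s.size and self.durations_s.min() <= 0:
            raise ValueError("event durations must be positive")
        bad = set(self.labels) - set(EVENT_LABELS)
        if bad:
            raise ValueError(f"unknown posture labels: {sorted(bad)}")
        if self.provenance in ("device", "registered-simulator"):
            # the first event may be a truncated tail of an earlier posture
            if len(self.durations_s) > 1 and (
                self.durations_s[1:].min() < self.MIN_REGISTERED_S - 1e-9
            ):
                raise ValueError(
                    "registered events must last >= 10 s (inclinometer rule)"
                )

    def __len__(self) -> int:
        return len(self.durations_s)

    @property
    def starts_s(self) -> np.ndarray:
        """Event start offsets in seconds from ``start_time``."""
        out = np.zeros(len(self), dtype=np.float64)
        if len(self) > 1:
            out[1:] = np.cumsum(self.durations_s[:-1])
        return out

    @property
    def total_duration_s(self) -> float:
        return float(self.durations_s.sum())

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.total_duration_s)


@dataclass
class EpochLabelSeries:
    """Contiguous fixed-width epochs labeled SIT / NONSIT / UNWORN.

    ``probs`` holds the model's sitting probability per epoch when the
    source is the classifier ("chap"); the decision rule is strict:
    label is SIT iff prob > 0.5.
    """

    start_time: datetime
    epoch_s: int
    labels: np.ndarray
    probs: np.ndarray | None = None
    source: str = "activpal"

    def __post_init__(self) -> None:
        if self.epoch_s not in (10, 60):
            raise ValueError(f"epoch_s must be 10 or 60, got {self.epoch_s}")
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(EPOCH_LABELS)
        if bad:
            raise ValueError(f"unknown epoch labels: {sorted(bad)}")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=np.float64)
            if len(self.probs) != len(self.labels):
                raise ValueError("probs/labels length mismatch")
            finite = np.isfinite(self.probs)
            if self.probs.size and (
                self.probs[finite].size
                and (self.probs[finite].min() < 0 or self.probs[finite].max() > 1)
            ):
                raise ValueError("probabilities must lie in [0, 1]")
            if self.source == "chap":
                worn = self.labels != UNWORN
                want_sit = self.probs[worn] > 0.5
                is_sit = self.labels[worn] == SIT
                if not np.array_equal(want_sit, is_sit):
                    raise ValueError(
                        "chap labels must satisfy SIT <=> prob > 0.5"
                    )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.epoch_s * len(self))

    def epoch_starts(self) -> list[datetime]:
        return [
            self.start_time + timedelta(seconds=self.epoch_s * i)
            for i in range(len(self))
        ]


# ---------------------------------------------------------------------------
# ActiGraph RAW CSV
# ---------------------------------------------------------------------------

_HEADER_LINES = 10


def _actigraph_header(
    start: datetime, rate_hz: float, epoch: str, serial: str
) -> list[str]:
    return [
        "------------ Data File Created By ActiGraph GT3X+ ActiLife "
        f"v6.13.3 Firmware v3.2.1 date format yyyy-MM-dd at {rate_hz:g} Hz "
        "Filter Normal -----------",
        f"Serial Number: {serial}",
        f"Start Time {start.strftime('%H:%M:%S')}",
        f"Start Date {start.strftime('%Y-%m-%d')}",
        f"Epoch Period (hh:mm:ss) {epoch}",
        "Download Time 00:00:00",
        f"Download Date {start.strftime('%Y-%m-%d')}",
        "Current Memory Address: 0",
        "Current Battery Voltage: 4.1     Mode = 12",
        "--------------------------------------------------",
    ]


def _parse_actigraph_header(lines: list[str], path) -> tuple[datetime, float, str]:
    if len(lines) < _HEADER_LINES:
        raise ParseError(f"{path}: truncated ActiGraph header")
    m = re.search(r"at ([\d.]+) Hz", lines[0])
    rate = float(m.group(1)) if m else float("nan")
    dm = re.search(r"date format (\S+)", lines[0])
    date_fmt = dm.group(1) if dm else "yyyy-MM-dd"
    start_time = start_date = None
    serial = ""
    for ln in lines[:_HEADER_LINES]:
        if ln.startswith("Start Time"):
            start_time = ln.split("Start Time", 1)[1].strip()
        elif ln.startswith("Start Date"):
            start_date = ln.split("Start Date", 1)[1].strip()
        elif ln.startswith("Serial Number:"):
            serial = ln.split(":", 1)[1].strip()
    if start_time is None or start_date is None:
        raise ParseError(f"{path}: header lacks Start Time / Start Date")
    py_fmt = {
        "yyyy-MM-dd": "%Y-%m-%d",
        "M/d/yyyy": "%m/%d/%Y",
        "d/M/yyyy": "%d/%m/%Y",
    }.get(date_fmt, "%Y-%m-%d")
    try:
        start = datetime.strptime(f"{start_date} {start_time}", f"{py_fmt} %H:%M:%S")
    except ValueError as e:
        raise ParseError(f"{path}: cannot parse start timestamp: {e}") from e
    return start, rate, serial


def write_actigraph_raw(stream: RawTriaxialStream, path, timestamps: bool = False) -> None:
    """Write an ActiGraph-style RAW CSV (g units, %.8e keeps float32 exact)."""
    path = Path(path)
    header = _actigraph_header(
        stream.start_time, stream.rate_hz, "00:00:00", stream.device_id or "SYN000"
    )
    cols = ["Accelerometer X", "Accelerometer Y", "Accelerometer Z"]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        if timestamps:
            fh.write("Timestamp," + ",".join(cols) + "\n")
            step = 1.0 / stream.rate_hz
            for i, row in enumerate(stream.samples):
                t = stream.start_time + timedelta(seconds=i * step)
                fh.write(
                    t.strftime("%Y-%m-%d %H:%M:%S.%f")[:-3]
                    + ","
                    + ",".join(f"{v:.8e}" for v in row)
                    + "\n"
                )
        else:
            fh.write(",".join(cols) + "\n")
            np.savetxt(fh, stream.samples, fmt="%.8e", delimiter=",")


def read_actigraph_raw(path, expected_rate: float = 30.0) -> RawTriaxialStream:
    """Read an ActiGraph RAW CSV, enforcing a constant ``expected_rate``.

    Accepts both the with-timestamp and without-timestamp body variants.
    Raises :class:`RateMismatchError` when the header rate disagrees with
    ``expected_rate`` and :class:`ParseError` for non-monotone timestamps.
    """
    path = Path(path)
    with open(path) as fh:
        head = [fh.readline().rstrip("\n") for _ in range(_HEADER_LINES)]
    start, rate, serial = _parse_actigraph_header(head, path)
    if not np.isclose(rate, expected_rate):
        raise RateMismatchError(
            f"{path}: rate mismatch: header {rate:g} Hz, expected {expected_rate:g} Hz"
        )
    df = pd.read_csv(path, skiprows=_HEADER_LINES)
    if df.shape[1] not in (3, 4):
        raise ParseError(f"{path}: expected 3 or 4 data columns, got {df.shape[1]}")
    if df.shape[1] == 4:
        ts = pd.to_datetime(df.iloc[:, 0])
        if len(ts) > 1:
            deltas = ts.diff().dropna().dt.total_seconds().to_numpy()
            if (deltas <= 0).any():
                raise ParseError(f"{path}: non-monotone timestamps")
            if not np.allclose(deltas, 1.0 / expected_rate, atol=2e-3):
                raise ParseError(f"{path}: sampling gaps (non-constant intervals)")
        data = df.iloc[:, 1:4]
    else:
        data = df
    samples = data.to_numpy(dtype=np.float32)
    return RawTriaxialStream(start, expected_rate, samples, device_id=serial)


# ---------------------------------------------------------------------------
# ActiGraph 60-s counts CSV
# ---------------------------------------------------------------------------

#: column headers recognised as the vertical counts axis, tried in order
COUNTS_COLUMN_MAP = ("Axis1", "axis1", "activity", "Activity", "counts", "Vertical")


def write_actigraph_counts(counts: CountsStream, path) -> None:
    path = Path(path)
    header = _actigraph_header(counts.start_time, 30, "00:01:00", "SYN000")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        cols = ["Axis1"]
        data = [counts.counts_vertical]
        if counts.counts_x2 is not None:
            cols.append("Axis2")
            data.append(counts.counts_x2)
        if counts.counts_x3 is not None:
            cols.append("Axis3")
            data.append(counts.counts_x3)
        fh.write(",".join(cols) + "\n")
        np.savetxt(fh, np.column_stack(data), fmt="%d", delimiter=",")


def read_actigraph_counts(path, column_map=COUNTS_COLUMN_MAP) -> CountsStream:
    """Read a 60-s epoch counts CSV; the epoch period must declare 60 s."""
    path = Path(path)
    with open(path) as fh:
        head = [fh.readline().rstrip("\n") for _ in range(_HEADER_LINES)]
    start, _rate, _serial = _parse_actigraph_header(head, path)
    for ln in head:
        if ln.startswith("Epoch Period"):
            m = re.search(r"(\d\d):(\d\d):(\d\d)", ln)
            if m:
                epoch = 3600 * int(m.group(1)) + 60 * int(m.group(2)) + int(m.group(3))
                if epoch != 60:
                    raise ParseError(
                        f"{path}: counts epoch must be 60 s, header declares {epoch} s"
                    )
    df = pd.read_csv(path, skiprows=_HEADER_LINES)
    col = next((c for c in column_map if c in df.columns), None)
    if col is None:
        numeric = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
        if not numeric:
            raise ParseError(f"{path}: no counts column found")
        col = numeric[0]
    vals = df[col].to_numpy()
    if (vals < 0).any():
        raise ParseError(f"{path}: negative counts")
    x2 = df["Axis2"].to_numpy() if "Axis2" in df.columns else None
    x3 = df["Axis3"].to_numpy() if "Axis3" in df.columns else None
    return CountsStream(start, vals, 60, x2, x3)


# ---------------------------------------------------------------------------
# activPAL events CSV
# ---------------------------------------------------------------------------

_AP_CODE = {0: SIT, 1: UPRIGHT, 2: UPRIGHT}
_AP_COLS = (
    "Time",
    "DataCount (samples)",
    "Interval (s)",
    "ActivityCode (0=sedentary 1=standing 2=stepping)",
)


def write_activpal_events(events: PostureEventList, path, rate_hz: float = 20.0) -> None:
    """Write a classic activPAL events export.

    SIT events get code 0; UPRIGHT events alternate codes 1/2 is not
    recoverable from the two-level representation, so code 1 is used.
    """
    path = Path(path)
    starts = events.starts_s
    with open(path, "w") as fh:
        fh.write(",".join(_AP_COLS) + "\n")
        for s, d, lab in zip(starts, events.durations_s, events.labels):
            ds = int(round(float(s) * 10))  # integer deciseconds avoid drift
            t = events.start_time + timedelta(seconds=ds // 10)
            code = 0 if lab == SIT else 1
            fh.write(
                f"{t.strftime(_TS_FMT)}.{ds % 10},"
                f"{int(round(s * rate_hz))},{d:.1f},{code}\n"
            )


def read_activpal_events(path) -> PostureEventList:
    """Read a classic activPAL events CSV into SIT/UPRIGHT intervals.

    Codes 1 (stand) and 2 (step) collapse to UPRIGHT; adjacent same-label
    events are kept separate (merging is a preprocessing concern).
    Non-contiguous or overlapping intervals raise :class:`ContiguityError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    time_col = next((c for c in df.columns if c.lower().startswith("time")), None)
    dur_col = next((c for c in df.columns if c.lower().startswith("interval")), None)
    code_col = next((c for c in df.columns if c.lower().startswith("activitycode")), None)
    if time_col is None or dur_col is None or code_col is None:
        raise ParseError(f"{path}: missing Time / Interval / ActivityCode columns")
    times = pd.to_datetime(df[time_col])
    durs = df[dur_col].to_numpy(dtype=np.float64)
    codes = df[code_col].to_numpy()
    labels = []
    for c in codes:
        if int(c) not in _AP_CODE:
            raise ParseError(f"{path}: unknown activity code {c}")
        labels.append(_AP_CODE[int(c)])
    if len(times) > 1:
        elapsed = (times - times.iloc[0]).dt.total_seconds().to_numpy()
        expected = np.concatenate([[0.0], np.cumsum(durs[:-1])])
        gaps = elapsed - expected
        if (gaps > 0.05).any():
            raise ContiguityError(f"{path}: non-contiguous events (gap detected)")
        if (gaps < -0.05).any():
            raise ContiguityError(f"{path}: overlapping events")
    start = times.iloc[0].to_pydatetime() if len(times) else datetime(2000, 1, 1)
    return PostureEventList(start, durs, np.array(labels, dtype=object), "device")


# ---------------------------------------------------------------------------
# pipeline epoch predictions
# ---------------------------------------------------------------------------


def write_epoch_predictions(series: EpochLabelSeries, path) -> None:
    """Write timestamp,label,probability rows; probabilities round-trip exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# epoch_s={series.epoch_s} source={series.source}\n")
        fh.write("timestamp,label,probability\n")
        for i, lab in enumerate(series.labels):
            t = series.start_time + timedelta(seconds=series.epoch_s * i)
            p = "" if series.probs is None else repr(float(series.probs[i]))
            fh.write(f"{t.strftime(_TS_FMT)},{lab},{p}\n")


def read_epoch_predictions(path) -> EpochLabelSeries:
    path = Path(path)
    with open(path) as fh:
        meta = fh.readline().strip()
        m = re.match(r"#\s*epoch_s=(\d+)\s+source=(\S+)", meta)
        if not m:
            raise ParseError(f"{path}: missing epoch metadata line")
        epoch_s, source = int(m.group(1)), m.group(2)
        df = pd.read_csv(fh)
    bad = set(df["label"]) - set(EPOCH_LABELS)
    if bad:
        raise ParseError(f"{path}: labels outside vocabulary: {sorted(bad)}")
    start = pd.to_datetime(df["timestamp"].iloc[0]).to_pydatetime()
    probs = None
    if df["probability"].notna().any():
        probs = df["probability"].to_numpy(dtype=np.float64)
    return EpochLabelSeries(
        start, epoch_s, df["label"].to_numpy(dtype=object), probs, source
    )


# ---------------------------------------------------------------------------
# participant-season summary CSV
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "participant",
    "season",
    "valid_days",
    "total_sed_min_day",
    "breaks_per_day",
    "min_day_bouts_ge30",
    "mean_bout_min",
    "usual_bout_min",
    "alpha",
    "source",
]


def write_summaries(rows: list[dict], path) -> None:
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_summaries(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: summary CSV lacks columns {sorted(missing)}")
    return df
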