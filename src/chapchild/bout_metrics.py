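"""Sitting bouts and the six participant-season sedentary variables.

A sedentary bout is a maximal run of consecutive SIT epochs (minimum one
epoch, no interruption tolerance); UNWORN terminates a bout without
creating a break. The six variables per participant-season are: total
sedentary time (min/day), breaks in sedentary time (n/day), time in bouts
>= 30 min (min/day), mean bout duration (min), usual bout duration (min,
the duration-weighted median — the bout length at which 50 % of sitting
time is accumulated), and alpha, the maximum-likelihood power-law exponent
of the bout-duration distribution (lower alpha = more time in long bouts).

The legacy counts comparator labels a minute sedentary iff the vertical
axis is under 100 counts (strict: exactly 100 → non-sedentary).

Mean/usual bout duration and alpha are computed on the bout list pooled
across a participant-season's valid days (per-day power-law fits are
unstable below ~50 bouts); per-day variables are averaged across valid
days. A valid day has >= 8 h (480 min) of simultaneous two-monitor wear,
and a participant-season needs >= 3 valid days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np

from chapchild.io_formats import NONSIT, SIT, UNWORN, CountsStream, EpochLabelSeries
from chapchild.preprocess import WearMask

CPM_THRESHOLD = 100
VALID_DAY_MIN = 480.0
MIN_VALID_DAYS = 3
BOUT_GE_MIN = 30.0


@dataclass
class BoutRecord:
    start_time: datetime
    duration_min: float


@dataclass
class DayStats:
    date: date
    wear_min: float
    sed_min: float
    breaks_n: int
    min_in_bouts_ge30: float
    bout_durations_min: list[float] = field(default_factory=list)


@dataclass
class ParticipantSeasonSummary:
    participant: str
    season: str
    valid_days_n: int
    total_sed_min_day: float
    breaks_per_day: float
    min_day_in_bouts_ge30: float
    mean_bout_min: float
    usual_bout_min: float
    alpha: float
    source: str = "activpal"

    def as_row(self) -> dict:
        return {
            "participant": self.participant,
            "season": self.season,
            "valid_days": self.valid_days_n,
            "total_sed_min_day": self.total_sed_min_day,
            "breaks_per_day": self.breaks_per_day,
            "min_day_bouts_ge30": self.min_day_in_bouts_ge30,
            "mean_bout_min": self.mean_bout_min,
            "usual_bout_min": self.usual_bout_min,
            "alpha": self.alpha,
            "source": self.source,
        }


def classify_cpm(counts: CountsStream, threshold: int = CPM_THRESHOLD) -> EpochLabelSeries:
    """Sedentary iff vertical counts < threshold (strict)."""
    labels = np.where(counts.counts_vertical < threshold, SIT, NONSIT).astype(object)
    return EpochLabelSeries(counts.start_time, 60, labels, None, source="cpm")


def segment_bouts(series: EpochLabelSeries) -> list[BoutRecord]:
    """Maximal runs of SIT epochs; UNWORN or NONSIT ends a bout."""
    bouts = []
    run_start = None
    run_len = 0
    for i, lab in enumerate(series.labels):
        if lab == SIT:
            if run_start is None:
                run_start = i
            run_len += 1
        else:
            if run_start is not None:
                bouts.append(_bout(series, run_start, run_len))
            run_start, run_len = None, 0
    if run_start is not None:
        bouts.append(_bout(series, run_start, run_len))
    return bouts


def _bout(series: EpochLabelSeries, start_idx: int, n_epochs: int) -> BoutRecord:
    t = series.start_time + timedelta(seconds=series.epoch_s * start_idx)
    return BoutRecord(t, n_epochs * series.epoch_s / 60.0)


def count_breaks(series: EpochLabelSeries) -> int:
    """SIT epochs immediately followed by NONSIT (UNWORN or series end: no break)."""
    lab = series.labels
    if len(lab) < 2:
        return 0
    return int(((lab[:-1] == SIT) & (lab[1:] == NONSIT)).sum())


def usual_bout_duration(durations_min) -> float:
    """Duration-weighted median, lower convention.

    The smallest bout duration x such that bouts of duration <= x
    accumulate at least half of total sitting time.
    """
    d = np.sort(np.asarray(durations_min, dtype=np.float64))
    if d.size == 0:
        raise ValueError("usual bout duration needs at least one bout")
    cum = np.cumsum(d)
    half = cum[-1] / 2.0
    return float(d[np.searchsorted(cum, half - 1e-12)])


def alpha(durations_min, xmin_min: float) -> float:
    """Continuous maximum-likelihood power-law exponent.

    alpha = 1 + n / sum(ln(x_i / xmin)); xmin is the method's minimum bout
    (10/60 min for the inclinometer and the classifier, 1 min for cpm).
    """
    x = np.asarray(durations_min, dtype=np.float64)
    if x.size < 2:
        raise ValueError("alpha needs at least two bouts")
    if (x < xmin_min - 1e-9).any():
        raise ValueError("all durations must be >= xmin")
    logsum = np.log(x / xmin_min).sum()
    if logsum <= 0:
        raise ValueError("alpha undefined: all bouts equal xmin")
    return float(1.0 + x.size / logsum)


def sample_power_law(
    n: int, alpha_true: float, xmin: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draws from the continuous power law p(x) ∝ x^-alpha, x >= xmin."""
    u = rng.random(n)
    return xmin * (1.0 - u) ** (-1.0 / (alpha_true - 1.0))


def summarize_day(series: EpochLabelSeries, wear_mask: WearMask | None = None) -> DayStats:
    """Daily sedentary totals from one calendar day's epoch series."""
    bouts = segment_bouts(series)
    durations = [b.duration_min for b in bouts]
    sed_min = float((series.labels == SIT).sum() * series.epoch_s / 60.0)
    ge30 = float(sum(d for d in durations if d >= BOUT_GE_MIN))
    if wear_mask is not None:
        wear_min = wear_mask.total_seconds() / 60.0
    else:
        wear_min = float((series.labels != UNWORN).sum() * series.epoch_s / 60.0)
    return DayStats(
        date=series.start_time.date(),
        wear_min=wear_min,
        sed_min=sed_min,
        breaks_n=count_breaks(series),
        min_in_bouts_ge30=ge30,
        bout_durations_min=durations,
    )


def summarize_participant_season(
    day_stats: list[DayStats],
    participant: str,
    season: str,
    source: str,
    xmin_min: float,
    valid_day_min: float = VALID_DAY_MIN,
    min_valid_days: int = MIN_VALID_DAYS,
) -> ParticipantSeasonSummary | None:
    """Average per-day variables over valid days; pool bouts for the pattern stats.

    Returns ``None`` when fewer than ``min_valid_days`` days reach
    ``valid_day_min`` minutes of simultaneous wear (participant-season
    excluded), or when alpha is undefined on the pooled bouts.
    """
    valid = [d for d in day_stats if d.wear_min >= valid_day_min]
    if len(valid) < min_valid_days:
        return None
    pooled = [d for day in valid for d in day.bout_durations_min]
    if len(pooled) < 2:
        return None
    try:
        a = alpha(pooled, xmin_min)
    except ValueError:
        return None
    return ParticipantSeasonSummary(
        participant=participant,
        season=season,
        valid_days_n=len(valid),
        total_sed_min_day=float(np.mean([d.sed_min for d in valid])),
        breaks_per_day=float(np.mean([d.breaks_n for d in valid])),
        min_day_in_bouts_ge30=float(np.mean([d.min_in_bouts_ge30 for d in valid])),
        mean_bout_min=float(np.mean(pooled)),
        usual_bout_min=usual_bout_duration(pooled),
        alpha=a,
        source=source,
    )
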