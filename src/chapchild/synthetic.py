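"""Simulated child participant-seasons: posture events, hip acceleration, counts.

The generator is an alternating-renewal process. Sitting bout durations
follow a continuous power law (default exponent 1.40, minimum 10 s — the
scale reported for children's inclinometer data), so the power-law alpha,
usual bout duration and bout MAPEs all have known ground truth. Upright
durations are the preceding sitting duration scaled by the odds
(1 − p_sit)/p_sit and a mean-one lognormal factor, which pins the realized
sitting fraction at ``p_sit_time`` even though the sitting distribution is
heavy-tailed.

The thigh inclinometer's behaviour is emulated by the 10-s registration
rule: a new posture lasting under 10 s fails to register and is absorbed
into the preceding registered posture.

The hip signal is gravity tilted by a posture-dependent angle plus sensor
noise, walking oscillation during upright bouts and occasional small
fidgets during sitting; "easy" difficulty guarantees that every upright
window has more dynamic variance than any sitting window (a variance
threshold alone separates the classes), "hard" shrinks the tilt separation
and modulates walking into bursts. Counts integrate the dead-banded,
high-passed vertical axis per minute, so still periods give zero-count
minutes and walking minutes exceed the 100 cpm cut-point.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from chapchild import bout_metrics, preprocess
from chapchild.io_formats import (
    SIT,
    UPRIGHT,
    CountsStream,
    PostureEventList,
    RawTriaxialStream,
    write_actigraph_counts,
    write_actigraph_raw,
    write_activpal_events,
)

GRAVITY_AXIS = 1  # y is the (negative) vertical axis when standing

#: signal parameters per difficulty level
_DIFFICULTY = {
    "easy": dict(
        tilt_sit_deg=45.0,
        tilt_stand_deg=5.0,
        tilt_jitter_deg=0.0,
        walk_amp_lo=0.2,
        walk_amp_hi=0.5,
        walk_duty=1.0,
        fidget_amp=0.08,
        fidget_rate_per_s=0.08,
        noise_sd=0.01,
    ),
    "hard": dict(
        tilt_sit_deg=20.0,
        tilt_stand_deg=10.0,
        tilt_jitter_deg=6.0,
        walk_amp_lo=0.05,
        walk_amp_hi=0.4,
        walk_duty=0.6,
        fidget_amp=0.12,
        fidget_rate_per_s=0.15,
        noise_sd=0.02,
    ),
}


@dataclass
class SimConfig:
    n_participants: int = 4
    days_per_participant: int = 5
    day_wear_hours: float = 12.0
    sit_alpha_true: float = 1.40
    sit_xmin_s: float = 10.0
    upright_lognorm_mu: float | None = None  # None → −sigma²/2 (mean-one factor)
    upright_lognorm_sigma: float = 0.5
    p_sit_time: float = 0.62
    participant_sit_sd: float = 0.06  # between-child SD of the sitting fraction
    difficulty: str = "easy"
    season: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sit_alpha_true <= 1:
            raise ValueError("sit_alpha_true must exceed 1")
        if not 0 < self.p_sit_time < 1:
            raise ValueError("p_sit_time must lie in (0, 1)")
        if self.sit_xmin_s <= 0 or self.day_wear_hours < 0:
            raise ValueError("durations must be positive")
        if self.difficulty not in _DIFFICULTY:
            raise ValueError(f"difficulty must be one of {sorted(_DIFFICULTY)}")

    @property
    def upright_mu(self) -> float:
        if self.upright_lognorm_mu is not None:
            return self.upright_lognorm_mu
        return -0.5 * self.upright_lognorm_sigma**2


def _rng(cfg: SimConfig, participant: int, day: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, participant, day, stream])


def _day_start(cfg: SimConfig, day: int) -> datetime:
    return datetime(2022, 3, 1, 8, 0, 0) + timedelta(days=day)


def participant_sit_fraction(cfg: SimConfig, participant: int) -> float:
    """Per-child target sitting fraction, Normal(p_sit_time, participant_sit_sd)."""
    rng = np.random.default_rng([cfg.seed, participant, 999, 9])
    return float(
        np.clip(rng.normal(cfg.p_sit_time, cfg.participant_sit_sd), 0.2, 0.95)
    )


def simulate_posture_events(cfg: SimConfig, participant: int, day: int) -> PostureEventList:
    """Exact (pre-registration) alternating SIT/UPRIGHT events for one day.

    Day construction works from a sitting-time budget: pure power-law
    sitting bouts are drawn until they fill ``p_i * day_wear_hours`` (the
    last draw censored at the budget), and each sitting bout brings an
    upright partner ``u_i = s_i * (1 - p_i)/p_i * LogNormal`` with a
    mean-one noise factor.  This pins the realized sitting fraction at the
    child's target ``p_i`` even though the sitting distribution is heavy
    tailed, while leaving all but one bout per day exact power-law draws.
    The realized day length therefore varies around ``day_wear_hours`` the
    way real wear time does. The starting posture alternates from a random
    per-day choice.
    """
    rng = _rng(cfg, participant, day, 0)
    start = _day_start(cfg, day)
    total = cfg.day_wear_hours * 3600.0
    empty = PostureEventList(
        start, np.empty(0), np.empty(0, dtype=object), provenance="simulator"
    )
    if total <= 0:
        return empty
    p_i = participant_sit_fraction(cfg, participant)
    budget = round(p_i * total, 1)
    sits: list[float] = []
    acc = 0.0
    while acc < budget:
        d = float(
            bout_metrics.sample_power_law(1, cfg.sit_alpha_true, cfg.sit_xmin_s, rng)[0]
        )
        d = round(d, 1)
        remaining = round(budget - acc, 1)
        if d >= remaining:  # censor the final bout at the budget
            if remaining < cfg.sit_xmin_s and sits:
                sits[-1] = round(sits[-1] + remaining, 1)
            else:
                sits.append(remaining)
            acc = budget
        else:
            sits.append(d)
            acc = round(acc + d, 1)
    odds = (1.0 - p_i) / p_i
    ups = [
        max(0.1, round(s * odds * float(rng.lognormal(cfg.upright_mu, cfg.upright_lognorm_sigma)), 1))
        for s in sits
    ]
    sit_first = rng.random() < 0.5
    durs: list[float] = []
    labs: list[str] = []
    for s, u in zip(sits, ups):
        pair = [(s, SIT), (u, UPRIGHT)] if sit_first else [(u, UPRIGHT), (s, SIT)]
        for dur, lab in pair:
            durs.append(dur)
            labs.append(lab)
    return PostureEventList(
        start,
        np.array(durs, dtype=np.float64),
        np.array(labs, dtype=object),
        provenance="simulator",
    )


def register_activpal(events: PostureEventList, min_posture_s: float = 10.0) -> PostureEventList:
    """Apply the inclinometer's 10-s registration rule.

    A new posture lasting under ``min_posture_s`` fails to register and is
    absorbed into the preceding registered posture; adjacent same-label
    events merge. The first event is kept even if short (nothing precedes
    it). Idempotent.
    """
    durs: list[float] = []
    labs: list[str] = []
    for d, lab in zip(events.durations_s, events.labels):
        if durs and (d < min_posture_s or lab == labs[-1]):
            # same-label events merge; a too-short posture change fails to
            # register and its time is credited to the preceding posture
            durs[-1] += d
        else:
            durs.append(d)
            labs.append(lab)
    return PostureEventList(
        events.start_time,
        np.array(durs, dtype=np.float64),
        np.array(labs, dtype=object),
        provenance="registered-simulator",
    )


def _event_sample_slices(events: PostureEventList, rate: float) -> np.ndarray:
    bounds = np.round(np.concatenate([[0.0], np.cumsum(events.durations_s)]) * rate)
    return bounds.astype(np.int64)


def synthesize_raw(
    events: PostureEventList, cfg: SimConfig, participant: int = 0, day: int = 0
) -> RawTriaxialStream:
    """30 Hz triaxial hip signal consistent with a posture event sequence."""
    p = _DIFFICULTY[cfg.difficulty]
    rng = _rng(cfg, participant, day, 1)
    rate = 30.0
    bounds = _event_sample_slices(events, rate)
    n = int(bounds[-1])
    sig = np.zeros((n, 3), dtype=np.float64)
    tgrid = np.arange(n) / rate
    for k in range(len(events)):
        lo, hi = bounds[k], bounds[k + 1]
        if hi <= lo:
            continue
        m = hi - lo
        sitting = events.labels[k] == SIT
        tilt = p["tilt_sit_deg"] if sitting else p["tilt_stand_deg"]
        tilt += rng.uniform(-p["tilt_jitter_deg"], p["tilt_jitter_deg"])
        th = np.deg2rad(tilt)
        grav = np.array([0.0, -np.cos(th), np.sin(th)])
        sig[lo:hi] = grav
        if sitting:
            # sparse fidget bumps, 0.4 s each, amplitude below the walking floor
            n_bumps = rng.poisson(p["fidget_rate_per_s"] * m / rate)
            for _ in range(n_bumps):
                b0 = lo + rng.integers(0, max(1, m))
                b1 = min(hi, b0 + 12)
                phase = rng.uniform(0, 2 * np.pi)
                osc = p["fidget_amp"] * np.sin(
                    2 * np.pi * 3.0 * tgrid[b0:b1] + phase
                )
                sig[b0:b1, GRAVITY_AXIS] += osc
        else:
            amp = rng.uniform(p["walk_amp_lo"], p["walk_amp_hi"])
            freq = rng.uniform(1.6, 2.4)
            phase = rng.uniform(0, 2 * np.pi)
            osc = amp * np.sin(2 * np.pi * freq * tgrid[lo:hi] + phase)
            if p["walk_duty"] < 1.0:
                # gate walking into ~1-s on/off bursts
                gate = np.repeat(rng.random(m // 30 + 1) < p["walk_duty"], 30)[:m]
                osc = osc * gate
            sig[lo:hi, GRAVITY_AXIS] += osc
            sig[lo:hi, 2] += 0.4 * osc
    sig += rng.normal(0.0, p["noise_sd"], size=sig.shape)
    return RawTriaxialStream(events.start_time, rate, sig.astype(np.float32), "SYN")


#: counts model: per-sample dead band (g) and integrator scale
COUNTS_DEADBAND_G = 0.05
COUNTS_SCALE = 30.0


def synthesize_counts(stream: RawTriaxialStream) -> CountsStream:
    """60-s vertical-axis counts from the 30 Hz stream.

    Per second the vertical axis is mean-centred (high-pass); absolute
    deviations above a dead band integrate into the minute's counts. A
    still minute yields exactly zero counts.
    """
    if not np.isclose(stream.rate_hz, 30.0):
        raise ValueError("counts are derived from the 30 Hz stream")
    n = stream.n_samples
    if n < 1800:
        raise ValueError("need at least one full minute of signal")
    n_sec = n // 30
    v = stream.samples[: n_sec * 30, GRAVITY_AXIS].astype(np.float64).reshape(n_sec, 30)
    hp = v - v.mean(axis=1, keepdims=True)
    excess = np.maximum(np.abs(hp) - COUNTS_DEADBAND_G, 0.0).sum(axis=1)
    n_min = n_sec // 60
    per_min = excess[: n_min * 60].reshape(n_min, 60).sum(axis=1)
    counts = np.round(COUNTS_SCALE * per_min).astype(np.int64)
    return CountsStream(stream.start_time, counts, 60)


# ---------------------------------------------------------------------------
# study bundles
# ---------------------------------------------------------------------------


@dataclass
class SimDay:
    participant: str
    day: int
    exact_events: PostureEventList
    registered_events: PostureEventList
    raw: RawTriaxialStream | None = None
    counts: CountsStream | None = None


@dataclass
class Study:
    cfg: SimConfig
    days: list[SimDay]
    truth_summaries: dict[str, bout_metrics.ParticipantSeasonSummary]

    def participants(self) -> list[str]:
        return sorted({d.participant for d in self.days})

    def participant_days(self, participant: str) -> list[SimDay]:
        return [d for d in self.days if d.participant == participant]


def truth_epoch_series(registered: PostureEventList, epoch_s: int = 10):
    """Ground-truth 10-s epoch labels from registered events."""
    start, seconds = preprocess.events_to_second_labels(registered)
    return preprocess.aggregate_to_epochs(seconds, start, epoch_s, source="activpal")


def _participant_truth(
    cfg: SimConfig, pid: str, days: list[SimDay]
) -> bout_metrics.ParticipantSeasonSummary | None:
    stats = []
    for d in days:
        series = truth_epoch_series(d.registered_events)
        stat = bout_metrics.summarize_day(series)
        # both monitors are worn for the whole simulated day
        stat.wear_min = d.registered_events.total_duration_s / 60.0
        stats.append(stat)
    return bout_metrics.summarize_participant_season(
        stats, pid, cfg.season, "activpal", xmin_min=10.0 / 60.0
    )


def make_study(
    cfg: SimConfig, outdir: str | Path | None = None, signals: bool = True
) -> Study:
    """Generate the full bundle; optionally write the three device files per day.

    ``signals=False`` skips the 30 Hz signal and counts synthesis for
    event-level work (oracle-classifier pipelines). Deterministic: the same
    config yields a byte-identical on-disk bundle.
    """
    days: list[SimDay] = []
    for pi in range(cfg.n_participants):
        pid = f"P{pi:02d}"
        for di in range(cfg.days_per_participant):
            exact = simulate_posture_events(cfg, pi, di)
            reg = register_activpal(exact)
            raw = synthesize_raw(exact, cfg, pi, di) if signals else None
            counts = synthesize_counts(raw) if signals else None
            days.append(SimDay(pid, di, exact, reg, raw, counts))
    truths = {}
    for pid in sorted({d.participant for d in days}):
        summ = _participant_truth(cfg, pid, [d for d in days if d.participant == pid])
        if summ is not None:
            truths[pid] = summ
    study = Study(cfg, days, truths)
    if outdir is not None:
        _write_bundle(study, Path(outdir))
    return study


def _write_bundle(study: Study, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(study.cfg), "participants": {}, "files": []}
    for d in study.days:
        stem = f"{d.participant}_day{d.day}"
        write_actigraph_raw(d.raw, outdir / f"{stem}_raw.csv")
        write_actigraph_counts(d.counts, outdir / f"{stem}_counts.csv")
        write_activpal_events(d.registered_events, outdir / f"{stem}_events.csv")
        manifest["files"].append(stem)
    for pid, summ in study.truth_summaries.items():
        manifest["participants"][pid] = summ.as_row()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def participant_windows(study: Study, participant: str):
    """Model-ready (windows, labels) for one participant, days concatenated.

    Windows come from the 30→10 Hz downsampled hip signal; labels from the
    registered inclinometer events via the second-level/≥6-s aggregation
    path. Lengths are matched per day before concatenation.
    """
    w_all, y_all = [], []
    for d in study.participant_days(participant):
        stream10 = preprocess.downsample_to_10hz(d.raw)
        wins = preprocess.stack_windows(preprocess.window_raw(stream10))
        series = truth_epoch_series(d.registered_events)
        n = min(len(wins), len(series.labels))
        w_all.append(wins[:n])
        y_all.append(series.labels[:n])
    return np.concatenate(w_all), np.concatenate(y_all)


def bundle_digest(outdir: str | Path) -> str:
    """SHA-256 over every file in a bundle (order-stable); for determinism checks."""
    h = hashlib.sha256()
    for f in sorted(Path(outdir).iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()
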