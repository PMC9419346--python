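"""End-to-end orchestration: simulate → classify → derive → evaluate.

The stages mirror a two-monitor validation study: hip-accelerometer
windows are classified by the CNN-BiLSTM (or by an oracle that replays the
inclinometer truth), wear time comes from the Choi algorithm on the 60-s
counts intersected with any supplied masks, bout variables are derived per
day and summarised per participant-season, and agreement against the
inclinometer is reported at the epoch, transition and participant-season
levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from chapchild import bout_metrics, evaluation, preprocess, synthetic
from chapchild.io_formats import (
    SIT,
    NONSIT,
    UNWORN,
    EpochLabelSeries,
    read_actigraph_counts,
    read_actigraph_raw,
    read_activpal_events,
)
from chapchild.nonwear_choi import ChoiParams, detect_nonwear
from chapchild.posture_model import (
    ModelConfig,
    PostureModel,
    TrainConfig,
    build_model,
    train,
)

SUMMARY_VARIABLES = [
    "total_sed_min_day",
    "breaks_per_day",
    "min_day_bouts_ge30",
    "mean_bout_min",
    "usual_bout_min",
    "alpha",
]


@dataclass
class PipelineConfig:
    """All tunables in one place; defaults are the study's stated parameters."""

    choi: ChoiParams = field(default_factory=ChoiParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    epoch_s: int = 10
    cpm_threshold: int = 100
    valid_day_min: float = 480.0
    min_valid_days: int = 3
    tolerance_s: float = 60.0


def load_study(bundle_dir: str | Path) -> synthetic.Study:
    """Reconstruct a Study from an on-disk bundle (exercises all readers)."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    cfg = synthetic.SimConfig(**manifest["config"])
    days = []
    for stem in manifest["files"]:
        pid, daytag = stem.split("_day")
        raw = read_actigraph_raw(bundle_dir / f"{stem}_raw.csv", expected_rate=30)
        counts = read_actigraph_counts(bundle_dir / f"{stem}_counts.csv")
        events = read_activpal_events(bundle_dir / f"{stem}_events.csv")
        days.append(
            synthetic.SimDay(pid, int(daytag), events, events, raw, counts)
        )
    truths = {}
    for pid, row in manifest["participants"].items():
        truths[pid] = bout_metrics.ParticipantSeasonSummary(
            participant=row["participant"],
            season=row["season"],
            valid_days_n=row["valid_days"],
            total_sed_min_day=row["total_sed_min_day"],
            breaks_per_day=row["breaks_per_day"],
            min_day_in_bouts_ge30=row["min_day_bouts_ge30"],
            mean_bout_min=row["mean_bout_min"],
            usual_bout_min=row["usual_bout_min"],
            alpha=row["alpha"],
            source=row["source"],
        )
    return synthetic.Study(cfg, days, truths)


def study_groups(study: synthetic.Study, participants: list[str]):
    """participant → (windows, labels) map for the model stage."""
    return {p: synthetic.participant_windows(study, p) for p in participants}


def train_on_study(
    study: synthetic.Study,
    train_pids: list[str],
    holdout_pids: list[str],
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
):
    model = build_model(mcfg or ModelConfig())
    return train(
        model,
        study_groups(study, train_pids),
        study_groups(study, holdout_pids),
        tcfg or TrainConfig(),
    )


def predict_day(model: PostureModel, day: synthetic.SimDay) -> EpochLabelSeries:
    """Classifier labels for one participant-day at 10-s epochs."""
    stream10 = preprocess.downsample_to_10hz(day.raw)
    wins = preprocess.stack_windows(preprocess.window_raw(stream10))
    return model.predict(wins, start_time=day.raw.start_time)


def oracle_day(day: synthetic.SimDay) -> EpochLabelSeries:
    """Replay the inclinometer truth as if it were the classifier's output."""
    series = synthetic.truth_epoch_series(day.registered_events)
    return EpochLabelSeries(
        series.start_time, series.epoch_s, series.labels, None, source="activpal"
    )


def cpm_day(day: synthetic.SimDay, threshold: int = 100) -> EpochLabelSeries:
    return bout_metrics.classify_cpm(day.counts, threshold)


def derive_summaries(
    study: synthetic.Study,
    labeler,
    source: str,
    xmin_min: float,
    cfg: PipelineConfig | None = None,
) -> dict[str, bout_metrics.ParticipantSeasonSummary]:
    """Per-participant-season summaries from any per-day labeling function.

    ``labeler(day) -> EpochLabelSeries``. Wear minutes per day are the
    bundle's stated wear (the simulator has no non-wear unless injected),
    so the ≥8-h valid-day rule applies on the same footing for every method.
    """
    cfg = cfg or PipelineConfig()
    out = {}
    for pid in study.participants():
        stats = []
        for day in study.participant_days(pid):
            series = labeler(day)
            stat = bout_metrics.summarize_day(series)
            stat.wear_min = day.registered_events.total_duration_s / 60.0
            stats.append(stat)
        summ = bout_metrics.summarize_participant_season(
            stats,
            pid,
            study.cfg.season,
            source,
            xmin_min=xmin_min,
            valid_day_min=cfg.valid_day_min,
            min_valid_days=cfg.min_valid_days,
        )
        if summ is not None:
            out[pid] = summ
    return out


def evaluate_epochs(
    study: synthetic.Study,
    model: PostureModel,
    test_pids: list[str],
    tolerance_s: float = 60.0,
) -> dict:
    """Per-participant confusion and transition metrics, then mean (SD)."""
    conf_rows, trans_rows = [], []
    for pid in test_pids:
        w, y = synthetic.participant_windows(study, pid)
        pred_series = model.predict(w)
        truth_series = EpochLabelSeries(
            pred_series.start_time, 10, np.asarray(y, dtype=object), None, "activpal"
        )
        conf_rows.append(evaluation.confusion_metrics(pred_series.labels, truth_series.labels))
        sens, ppv, _ = evaluation.transition_pairing(
            evaluation.extract_transitions(pred_series),
            evaluation.extract_transitions(truth_series),
            tolerance_s,
        )
        trans_rows.append({"sensitivity": sens, "ppv": ppv})
    conf_summary = evaluation.summarize_rows(
        conf_rows,
        ["sensitivity", "specificity", "balanced_accuracy", "ppv", "npv", "kappa"],
    )
    def _finite_mean(values):
        arr = np.asarray(values, dtype=np.float64)
        ok = np.isfinite(arr)
        return float(arr[ok].mean()) if ok.any() else float("nan")

    return {
        "epoch": conf_summary,
        "transitions": {
            "tolerance_s": tolerance_s,
            "sensitivity_mean": _finite_mean([r["sensitivity"] for r in trans_rows]),
            "ppv_mean": _finite_mean([r["ppv"] for r in trans_rows]),
        },
        "per_participant": {
            pid: {"balanced_accuracy": row.balanced_accuracy}
            for pid, row in zip(test_pids, conf_rows)
        },
    }


def evaluate_summaries(
    pred: dict[str, bout_metrics.ParticipantSeasonSummary],
    truth: dict[str, bout_metrics.ParticipantSeasonSummary],
) -> list[evaluation.AgreementRow]:
    pred_rows = {k: _vars(v) for k, v in pred.items()}
    truth_rows = {k: _vars(v) for k, v in truth.items()}
    return evaluation.agreement(pred_rows, truth_rows, SUMMARY_VARIABLES)


def _vars(s: bout_metrics.ParticipantSeasonSummary) -> dict:
    return {
        "total_sed_min_day": s.total_sed_min_day,
        "breaks_per_day": s.breaks_per_day,
        "min_day_bouts_ge30": s.min_day_in_bouts_ge30,
        "mean_bout_min": s.mean_bout_min,
        "usual_bout_min": s.usual_bout_min,
        "alpha": s.alpha,
    }


def wear_mask_for_day(day: synthetic.SimDay, choi: ChoiParams | None = None) -> preprocess.WearMask:
    """Choi wear intervals from the day's counts stream."""
    return detect_nonwear(day.counts, choi or ChoiParams())
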