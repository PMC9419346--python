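"""The CNN-BiLSTM posture classifier.

Per 10-s epoch, a small 1-D CNN extracts features from the 100 x 3 window
of 10 Hz acceleration; a bidirectional LSTM models how sitting and
non-sitting epochs occur in sequence; a softmax head emits the sitting
probability for every epoch.  The decision rule is strict: SIT iff
probability > 0.5 (probability exactly 0.5 → NONSIT).

Input windows are standardized per axis with training-set mean/SD stored
in the model bundle — the raw g offsets encode gravity direction (posture),
so per-window normalization would destroy the signal.

At prediction time every epoch is scored exactly once, from the stride-1
sequence in which it sits at the centre position; edge sequences are padded
by replicating the first/last window and the padded outputs are discarded.

Model-selection metric (both during early stopping and in the grid search):
the mean of (A) epoch-level balanced accuracy and (B) balanced accuracy for
sit-to-stand transitions between adjacent epochs, computed on held-out
participants.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import numpy as np

from chapchild import _nn
from chapchild.io_formats import NONSIT, SIT, EpochLabelSeries

FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    conv_channels: list[int] = field(default_factory=lambda: [32, 64])
    conv_kernel: int = 5
    pool: int = 2
    seq_len_epochs: int = 9
    rnn_hidden: int = 64
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_len_epochs < 1:
            raise ValueError("seq_len_epochs must be >= 1")
        if self.conv_kernel < 1 or self.pool < 1 or self.rnn_hidden < 1:
            raise ValueError("all model sizes must be positive")
        if not self.conv_channels or min(self.conv_channels) < 1:
            raise ValueError("conv_channels must be non-empty positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        length = 100
        for _ in self.conv_channels:
            length = (length - self.conv_kernel + 1) // self.pool
            if length < 1:
                raise ValueError("conv stack consumes the whole 100-sample window")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("train config values must be positive")


def balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean of sitting recall (sensitivity) and non-sitting recall (specificity)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    pos = truth == SIT if truth.dtype == object else truth == 1
    ppos = pred == SIT if pred.dtype == object else pred == 1
    sens = (ppos & pos).sum() / pos.sum() if pos.any() else np.nan
    spec = (~ppos & ~pos).sum() / (~pos).sum() if (~pos).any() else np.nan
    return float((sens + spec) / 2.0)


def transition_balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Balanced accuracy for SIT→NONSIT adjacencies between consecutive epochs."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(truth) < 2:
        return np.nan
    tp_pos = (truth[:-1] == 1) & (truth[1:] == 0) if truth.dtype != object else (
        (truth[:-1] == SIT) & (truth[1:] == NONSIT)
    )
    pp_pos = (pred[:-1] == 1) & (pred[1:] == 0) if pred.dtype != object else (
        (pred[:-1] == SIT) & (pred[1:] == NONSIT)
    )
    sens = (pp_pos & tp_pos).sum() / tp_pos.sum() if tp_pos.any() else np.nan
    spec = (~pp_pos & ~tp_pos).sum() / (~tp_pos).sum() if (~tp_pos).any() else np.nan
    return float(np.nanmean([sens, spec]))


class PostureModel:
    """CNN feature extractor + BiLSTM sequence model + softmax head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.fitted = False
        self.label_map = {0: NONSIT, 1: SIT}
        self.norm_mean = np.zeros(3)
        self.norm_sd = np.ones(3)
        rng = np.random.default_rng(cfg.seed)
        self.conv_stack: list = []
        c_in = 3
        for c_out in cfg.conv_channels:
            self.conv_stack.append(_nn.Conv1d(c_in, c_out, cfg.conv_kernel, rng))
            self.conv_stack.append(_nn.ReLU())
            self.conv_stack.append(_nn.MaxPool1d(cfg.pool))
            c_in = c_out
        self.conv_stack.append(_nn.GlobalAvgPool())
        self.feat_dim = c_in
        self.drop = _nn.Dropout(cfg.dropout)
        self.rnn = _nn.BiLSTM(self.feat_dim, cfg.rnn_hidden, rng)
        self.head = _nn.Dense(2 * cfg.rnn_hidden, 2, rng)

    # -- plumbing -----------------------------------------------------------

    @property
    def layers(self) -> list:
        return [*self.conv_stack, self.drop, self.rnn, self.head]

    def _param_layers(self):
        out = []
        for l in self.layers:
            if isinstance(l, _nn.BiLSTM):
                out.extend(l.sublayers)
            elif l.params:
                out.append(l)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self._param_layers() for p in l.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self._param_layers()):
            for k, v in l.params.items():
                out[f"layer{i}.{k}"] = v.copy()
        out["norm_mean"] = self.norm_mean.copy()
        out["norm_sd"] = self.norm_sd.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self._param_layers()):
            for k in l.params:
                l.params[k][...] = state[f"layer{i}.{k}"]
        self.norm_mean = np.asarray(state["norm_mean"], dtype=np.float64)
        self.norm_sd = np.asarray(state["norm_sd"], dtype=np.float64)

    # -- forward / backward -------------------------------------------------

    def _normalize(self, windows: np.ndarray) -> np.ndarray:
        return (np.asarray(windows, dtype=np.float64) - self.norm_mean) / self.norm_sd

    def _conv_features(self, flat_windows: np.ndarray) -> np.ndarray:
        h = flat_windows
        for l in self.conv_stack:
            h = l.forward(h)
        return h

    def _forward_sequences(self, seqs: np.ndarray, train=False, rng=None) -> np.ndarray:
        b, t = seqs.shape[:2]
        feats = self._conv_features(seqs.reshape(b * t, 100, 3)).reshape(b, t, -1)
        feats = self.drop.forward(feats, train=train, rng=rng)
        hs = self.rnn.forward(feats)
        return self.head.forward(hs)

    def _backward(self, dlogits: np.ndarray) -> None:
        b, t = dlogits.shape[:2]
        dh = self.head.backward(dlogits)
        dfeat = self.rnn.backward(dh)
        dfeat = self.drop.backward(dfeat)
        d = dfeat.reshape(b * t, -1)
        for l in reversed(self.conv_stack):
            d = l.backward(d)

    # -- inference ----------------------------------------------------------

    def predict_proba(self, windows: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Sitting probability per window (stride-1, centre-assigned)."""
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        windows = self._normalize(windows)
        m = windows.shape[0]
        if m == 0:
            return np.empty(0)
        t = self.cfg.seq_len_epochs
        c = (t - 1) // 2
        feats = self._conv_features(windows)  # each window featurised once
        idx = np.clip(np.arange(m)[:, None] + np.arange(t)[None, :] - c, 0, m - 1)
        probs = np.empty(m)
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            seq_feats = feats[idx[lo:hi]]  # (b, t, F)
            hs = self.rnn.forward(seq_feats)
            logits = self.head.forward(hs)
            probs[lo:hi] = _nn.softmax(logits)[:, c, 1]
        return probs

    def predict(
        self, windows: np.ndarray, start_time: datetime | None = None, epoch_s: int = 10
    ) -> EpochLabelSeries:
        probs = self.predict_proba(windows)
        labels = np.where(probs > 0.5, SIT, NONSIT).astype(object)
        return EpochLabelSeries(
            start_time or datetime(2000, 1, 1), epoch_s, labels, probs, source="chap"
        )


def build_model(cfg: ModelConfig) -> PostureModel:
    return PostureModel(cfg)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _label_ints(labels) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    return (arr == SIT).astype(np.int64)


def _make_sequences(groups: dict[str, tuple[np.ndarray, np.ndarray]], t: int):
    """Chunk each participant's contiguous windows into disjoint length-t sequences."""
    xs, ys = [], []
    for _pid, (w, y) in groups.items():
        n = (len(w) // t) * t
        if n == 0:
            continue
        xs.append(w[:n].reshape(-1, t, 100, 3))
        ys.append(y[:n].reshape(-1, t))
    if not xs:
        raise ValueError("no training sequences (streams shorter than seq_len)")
    return np.concatenate(xs), np.concatenate(ys)


def selection_metric(model: PostureModel, holdout_groups) -> float:
    """Mean of epoch and transition balanced accuracies over held-out data."""
    bas, tbas = [], []
    for _pid, (w, y) in holdout_groups.items():
        probs = model.predict_proba(w)
        pred = (probs > 0.5).astype(np.int64)
        bas.append(balanced_accuracy(pred, y))
        tbas.append(transition_balanced_accuracy(pred, y))
    return float(np.nanmean(bas) + np.nanmean(tbas)) / 2.0


def train(
    model: PostureModel,
    train_groups: dict[str, tuple[np.ndarray, np.ndarray]],
    holdout_groups: dict[str, tuple[np.ndarray, np.ndarray]],
    tcfg: TrainConfig = TrainConfig(),
) -> tuple[PostureModel, list[dict]]:
    """Fit by Adam on cross-entropy; keep the best holdout checkpoint.

    ``train_groups`` / ``holdout_groups`` map participant id → (windows
    (n,100,3), labels (n,) of SIT/NONSIT strings or {0,1} ints).  Holdout
    participants must be disjoint from training participants.
    """
    if not holdout_groups:
        raise ValueError("empty holdout")
    overlap = set(train_groups) & set(holdout_groups)
    if overlap:
        raise ValueError(f"holdout participants overlap training: {sorted(overlap)}")
    train_groups = {
        p: (np.asarray(w, np.float64), _label_ints(y)) for p, (w, y) in train_groups.items()
    }
    holdout_groups = {
        p: (np.asarray(w, np.float64), _label_ints(y)) for p, (w, y) in holdout_groups.items()
    }
    all_y = np.concatenate([y for _, y in train_groups.values()])
    if len(np.unique(all_y)) < 2:
        raise ValueError("single class in training labels")

    all_w = np.concatenate([w for w, _ in train_groups.values()])
    model.norm_mean = all_w.reshape(-1, 3).mean(axis=0)
    model.norm_sd = all_w.reshape(-1, 3).std(axis=0)
    model.norm_sd[model.norm_sd < 1e-8] = 1.0
    train_groups = {p: (model._normalize(w), y) for p, (w, y) in train_groups.items()}

    xs, ys = _make_sequences(train_groups, model.cfg.seq_len_epochs)
    rng = np.random.default_rng(tcfg.seed)
    opt = _nn.Adam(model._param_layers(), lr=tcfg.lr)
    model.fitted = True  # allow selection-metric prediction mid-training

    history: list[dict] = []
    best_metric, best_state, since_best = -np.inf, model.state_dict(), 0
    n_seq = xs.shape[0]
    for ep in range(tcfg.max_epochs):
        order = rng.permutation(n_seq)
        losses = []
        for lo in range(0, n_seq, tcfg.batch_size):
            batch = order[lo : lo + tcfg.batch_size]
            opt.zero_grad()
            logits = model._forward_sequences(xs[batch], train=True, rng=rng)
            loss, dlogits = _nn.cross_entropy(logits, ys[batch])
            model._backward(dlogits)
            opt.step()
            losses.append(loss)
        metric = selection_metric(model, holdout_groups)
        history.append({"epoch": ep, "loss": float(np.mean(losses)), "holdout_metric": metric})
        if metric > best_metric + 1e-9:
            best_metric, best_state, since_best = metric, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= tcfg.patience:
                break
    model.load_state_dict(best_state)
    return model, history


def grid_select(
    candidates: list[ModelConfig],
    train_groups,
    selection_groups,
    tcfg: TrainConfig = TrainConfig(),
) -> tuple[ModelConfig, list[dict]]:
    """Train every candidate; return the config with the best selection metric.

    Ties (within 1e-9) break toward the model with fewer parameters.
    """
    if not candidates:
        raise ValueError("need at least one candidate config")
    report = []
    for cfg in candidates:
        model = build_model(cfg)
        model, _hist = train(model, train_groups, selection_groups, tcfg)
        report.append(
            {
                "config": cfg,
                "metric": selection_metric(model, {
                    p: (model._normalize(w), _label_ints(y))
                    for p, (w, y) in selection_groups.items()
                }),
                "n_parameters": model.n_parameters(),
            }
        )
    best = max(report, key=lambda r: (round(r["metric"] / 1e-9), -r["n_parameters"]))
    return best["config"], report


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: PostureModel, path) -> None:
    """Write a model bundle directory: params.npz + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "params.npz", **model.state_dict())
    sidecar = {
        "format_version": FORMAT_VERSION,
        "fitted": model.fitted,
        "label_map": {str(k): v for k, v in model.label_map.items()},
        "config": asdict(model.cfg),
    }
    (path / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> PostureModel:
    path = Path(path)
    sidecar = json.loads((path / "model.json").read_text())
    if sidecar["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"model bundle format v{sidecar['format_version']} != supported v{FORMAT_VERSION}"
        )
    cfg = ModelConfig(**sidecar["config"])
    model = PostureModel(cfg)
    with np.load(path / "params.npz") as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    model.fitted = bool(sidecar["fitted"])
    return model
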