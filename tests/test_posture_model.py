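"""CNN-BiLSTM contracts: shapes, gradients, determinism, persistence."""

import numpy as np
import pytest

from chapchild import _nn
from chapchild.posture_model import (
    ModelConfig,
    PostureModel,
    TrainConfig,
    balanced_accuracy,
    build_model,
    grid_select,
    load_model,
    save_model,
    train,
)

TINY = ModelConfig(
    conv_channels=[4, 6], conv_kernel=3, pool=2, seq_len_epochs=3,
    rnn_hidden=5, dropout=0.0, seed=0,
)


def toy_groups(rng, pids, n_windows=60, separation=1.0):
    """Synthetic-free toy data: SIT = tilted gravity + tiny noise, NONSIT = oscillation."""
    groups = {}
    for pid in pids:
        y = rng.integers(0, 2, n_windows)
        w = rng.normal(0, 0.02, (n_windows, 100, 3))
        w[:, :, 1] -= 1.0
        sit = y == 1
        w[sit, :, 2] += 0.6 * separation
        t = np.arange(100) / 10.0
        w[~sit, :, 1] += 0.3 * separation * np.sin(2 * np.pi * 2.0 * t)
        labels = np.where(y == 1, "SIT", "NONSIT").astype(object)
        groups[pid] = (w, labels)
    return groups


class TestBuildModel:
    def test_default_shapes(self):
        m = build_model(ModelConfig())
        x = np.random.default_rng(0).normal(size=(2, 9, 100, 3))
        logits = m._forward_sequences(x)
        assert logits.shape == (2, 9, 2)
        p = _nn.softmax(logits)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)

    def test_single_epoch_sequence(self):
        m = build_model(ModelConfig(seq_len_epochs=1))
        logits = m._forward_sequences(np.zeros((4, 1, 100, 3)))
        assert logits.shape == (4, 1, 2)

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_kernel=0)

    def test_unfitted_predict_refused(self):
        m = build_model(TINY)
        with pytest.raises(RuntimeError, match="not fitted"):
            m.predict_proba(np.zeros((5, 100, 3)))


class TestGradients:
    def test_finite_difference_check(self):
        m = PostureModel(TINY)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 3, 100, 3))
        y = rng.integers(0, 2, size=(2, 3))
        for l in m._param_layers():
            l.zero_grad()
        logits = m._forward_sequences(x)
        _, dl = _nn.cross_entropy(logits, y)
        m._backward(dl)

        def loss():
            return _nn.cross_entropy(m._forward_sequences(x), y)[0]

        eps = 1e-6
        for l in m._param_layers():
            for k, p in l.params.items():
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = l.grads[k][idx]
                assert num == pytest.approx(ana, rel=1e-3, abs=1e-7)


class TestTraining:
    def _fit(self, seed=0, **kw):
        rng = np.random.default_rng(100)
        groups = toy_groups(rng, ["a", "b"])
        hold = toy_groups(rng, ["h"])
        m = build_model(ModelConfig(**{**TINY.__dict__, "seed": seed}))
        tcfg = TrainConfig(max_epochs=kw.pop("max_epochs", 12), patience=6, seed=seed)
        return train(m, groups, hold, tcfg)

    def test_learns_separable_toy_data(self):
        m, hist = self._fit()
        rng = np.random.default_rng(200)
        w, y = toy_groups(rng, ["t"])["t"]
        probs = m.predict_proba(w)
        ba = balanced_accuracy((probs > 0.5).astype(int), (y == "SIT").astype(int))
        assert ba > 0.9

    def test_same_seed_identical_runs(self):
        m1, h1 = self._fit(seed=3)
        m2, h2 = self._fit(seed=3)
        assert h1 == h2
        s1, s2 = m1.state_dict(), m2.state_dict()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        groups = {"a": (rng.normal(size=(20, 100, 3)), np.array(["SIT"] * 20, object))}
        hold = toy_groups(rng, ["h"])
        with pytest.raises(ValueError, match="single class"):
            train(build_model(TINY), groups, hold, TrainConfig(max_epochs=1))

    def test_empty_holdout_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="holdout"):
            train(build_model(TINY), toy_groups(rng, ["a"]), {}, TrainConfig())

    def test_holdout_overlap_rejected(self):
        rng = np.random.default_rng(0)
        g = toy_groups(rng, ["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            train(build_model(TINY), g, {"a": g["a"]}, TrainConfig())


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(100)
    m, _ = train(
        build_model(TINY),
        toy_groups(rng, ["a", "b"]),
        toy_groups(rng, ["h"]),
        TrainConfig(max_epochs=3, patience=2, seed=0),
    )
    return m


class TestPredict:
    def test_probability_half_is_nonsit(self, fitted):
        from chapchild.io_formats import EpochLabelSeries
        from datetime import datetime

        s = EpochLabelSeries(
            datetime(2022, 3, 1), 10,
            np.array(["NONSIT", "SIT"], dtype=object), [0.5, 0.500001], "chap",
        )
        assert list(s.labels) == ["NONSIT", "SIT"]

    def test_deterministic_prediction(self, fitted):
        rng = np.random.default_rng(8)
        w = rng.normal(0, 0.3, (30, 100, 3))
        np.testing.assert_array_equal(fitted.predict_proba(w), fitted.predict_proba(w))

    def test_chunking_invariance(self, fitted):
        """Per-epoch outputs do not depend on prediction batch boundaries."""
        rng = np.random.default_rng(9)
        w = rng.normal(0, 0.3, (50, 100, 3))
        np.testing.assert_allclose(
            fitted.predict_proba(w, chunk=7), fitted.predict_proba(w, chunk=512), atol=1e-12
        )

    def test_label_rule_strict(self, fitted):
        rng = np.random.default_rng(10)
        w = rng.normal(0, 0.3, (20, 100, 3))
        out = fitted.predict(w)
        np.testing.assert_array_equal(out.labels == "SIT", out.probs > 0.5)


class TestPersistence:
    @pytest.mark.parametrize(
        "cfg",
        [
            TINY,
            ModelConfig(conv_channels=[3], conv_kernel=7, pool=3, seq_len_epochs=5,
                        rnn_hidden=4, dropout=0.1, seed=2),
            ModelConfig(conv_channels=[2, 2, 2], conv_kernel=3, pool=2,
                        seq_len_epochs=1, rnn_hidden=3, dropout=0.0, seed=5),
        ],
    )
    def test_round_trip_identical_predictions(self, tmp_path, cfg):
        rng = np.random.default_rng(cfg.seed)
        m, _ = train(
            build_model(cfg),
            toy_groups(rng, ["a", "b"], n_windows=30),
            toy_groups(rng, ["h"], n_windows=30),
            TrainConfig(max_epochs=2, patience=1, seed=cfg.seed),
        )
        save_model(m, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        w = rng.normal(0, 0.3, (25, 100, 3))
        np.testing.assert_array_equal(m.predict_proba(w), back.predict_proba(w))

    def test_version_mismatch_flagged(self, tmp_path):
        m = build_model(TINY)
        m.fitted = True
        save_model(m, tmp_path / "b")
        sidecar = (tmp_path / "b" / "model.json").read_text().replace(
            '"format_version": 1', '"format_version": 99'
        )
        (tmp_path / "b" / "model.json").write_text(sidecar)
        with pytest.raises(ValueError, match="format"):
            load_model(tmp_path / "b")


class TestGridSelect:
    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        best, report = grid_select(
            [TINY], toy_groups(rng, ["a", "b"]), toy_groups(rng, ["s"]),
            TrainConfig(max_epochs=2, patience=1, seed=0),
        )
        assert best == TINY and len(report) == 1

    def test_tie_prefers_fewer_parameters(self):
        # on perfectly separable data both candidates saturate the metric
        rng = np.random.default_rng(1)
        small = TINY
        big = ModelConfig(**{**TINY.__dict__, "rnn_hidden": 12})
        best, report = grid_select(
            [big, small],
            toy_groups(rng, ["a", "b"], separation=3.0),
            toy_groups(rng, ["s"], separation=3.0),
            TrainConfig(max_epochs=3, patience=2, seed=0),
        )
        metrics = [r["metric"] for r in report]
        if metrics[0] == pytest.approx(metrics[1], abs=1e-9):
            assert best == small

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            grid_select([], {}, {})
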