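"""Confusion metrics, transition pairing, Lin's CCC and agreement statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chapchild import evaluation as ev
from conftest import expand, series


def matching_oracle(pred, true, tol):
    """Exhaustive maximum bipartite matching by enumerating injective maps."""
    pred, true = list(pred), list(true)
    if len(true) <= len(pred):
        best = 0
        for perm in itertools.permutations(range(len(pred)), len(true)):
            best = max(
                best,
                sum(1 for ti, pi in enumerate(perm) if abs(pred[pi] - true[ti]) <= tol),
            )
        return best
    return matching_oracle(true, pred, tol)


def labels(pattern):
    return np.array(expand(pattern), dtype=object)


class TestConfusionMetrics:
    def test_printed_arithmetic(self):
        """sens 0.936 and spec 0.816 combine to balanced accuracy 0.876."""
        truth = ["SIT"] * 1000 + ["NONSIT"] * 1000
        pred = (
            ["SIT"] * 936 + ["NONSIT"] * 64 + ["NONSIT"] * 816 + ["SIT"] * 184
        )
        row = ev.confusion_metrics(np.array(pred, object), np.array(truth, object))
        assert row.sensitivity == pytest.approx(0.936)
        assert row.specificity == pytest.approx(0.816)
        assert row.balanced_accuracy == pytest.approx(0.876)

    def test_perfect_agreement(self):
        t = labels("SSNNSN")
        row = ev.confusion_metrics(t, t)
        for f in ("sensitivity", "specificity", "balanced_accuracy", "ppv", "npv", "kappa"):
            assert getattr(row, f) == pytest.approx(1.0)

    def test_complement_prediction(self):
        t = labels("SSNN")
        p = labels("NNSS")
        row = ev.confusion_metrics(p, t)
        assert row.sensitivity == 0.0 and row.specificity == 0.0
        assert row.kappa <= 0.0

    def test_zero_denominator_is_missing(self):
        row = ev.confusion_metrics(labels("NN"), labels("NN"))
        assert np.isnan(row.sensitivity) and np.isnan(row.ppv)
        assert row.specificity == 1.0

    def test_balanced_accuracy_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            t = rng.choice(["SIT", "NONSIT"], 40)
            p = rng.choice(["SIT", "NONSIT"], 40)
            row = ev.confusion_metrics(p.astype(object), t.astype(object))
            if np.isfinite(row.balanced_accuracy):
                assert row.balanced_accuracy == (row.sensitivity + row.specificity) / 2


class TestExtractTransitions:
    def test_single_transition_timestamp(self):
        assert list(ev.extract_transitions(series(expand("SN")))) == [10.0]

    def test_stand_to_sit_excluded(self):
        assert len(ev.extract_transitions(series(expand("NS")))) == 0

    def test_multiple(self):
        out = ev.extract_transitions(series(expand("SSNNSN")))
        np.testing.assert_array_equal(out, [20.0, 50.0])


class TestTransitionPairing:
    def test_identical_lists(self):
        s, p, m = ev.transition_pairing([10, 100], [10, 100], 60)
        assert (s, p) == (1.0, 1.0) and len(m) == 2

    def test_within_tolerance(self):
        s, p, _ = ev.transition_pairing([150.0], [100.0], 60)
        assert (s, p) == (1.0, 1.0)

    def test_extra_prediction_halves_ppv(self):
        s, p, _ = ev.transition_pairing([150.0, 170.0], [100.0], 60)
        assert (s, p) == (1.0, 0.5)

    def test_strictly_beyond_tolerance(self):
        s, p, _ = ev.transition_pairing([161.1], [100.0], 60)
        assert (s, p) == (0.0, 0.0)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            ev.transition_pairing([50, 10], [10], 60)

    def test_empty_truth_missing_sensitivity(self):
        s, p, _ = ev.transition_pairing([10.0], [], 60)
        assert np.isnan(s) and p == 0.0

    def test_chain_requires_lookback(self):
        # nearest-first greedy would match true 60 to pred 100 and strand true 150
        s, p, m = ev.transition_pairing([0.0, 100.0], [60.0, 150.0], 60)
        assert len(m) == 2 and (s, p) == (1.0, 1.0)

    def test_matches_exhaustive_oracle_random(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            pred = np.sort(rng.choice(np.arange(0, 601, 30), rng.integers(0, 5), replace=False))
            true = np.sort(rng.choice(np.arange(0, 601, 30), rng.integers(0, 5), replace=False))
            s, p, m = ev.transition_pairing(pred, true, 60)
            assert len(m) == matching_oracle(pred, true, 60)

    def test_symmetry_swapping_pred_true(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = np.sort(rng.uniform(0, 500, rng.integers(0, 6)))
            b = np.sort(rng.uniform(0, 500, rng.integers(0, 6)))
            s1, p1, m1 = ev.transition_pairing(a, b, 60)
            s2, p2, m2 = ev.transition_pairing(b, a, 60)
            assert len(m1) == len(m2)
            if len(a) and len(b):
                assert s1 == pytest.approx(p2) and p1 == pytest.approx(s2)

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pred = np.sort(rng.uniform(0, 3000, 8))
            true = np.sort(rng.uniform(0, 3000, 6))
            prev_s = prev_p = -1.0
            for tol in (30, 60, 120, 300):
                s, p, _ = ev.transition_pairing(pred, true, tol)
                assert s >= prev_s and p >= prev_p
                prev_s, prev_p = s, p


class TestLinCcc:
    def test_identity(self):
        x = np.arange(10.0)
        assert ev.lin_ccc(x, x) == pytest.approx(1.0)

    def test_shift_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 3.0, 500)
        c = 2.5
        s2 = x.var()
        assert ev.lin_ccc(x, x + c) == pytest.approx(2 * s2 / (2 * s2 + c**2), abs=1e-12)

    def test_perfect_reversal(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert ev.lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ev.lin_ccc([1.0, 1.0], [1.0, 1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
            min_size=3,
            max_size=30,
        )
    )
    def test_bounded_by_pearson(self, pairs):
        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        if x.var() < 1e-9 or y.var() < 1e-9:
            return
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ev.lin_ccc(x, y)) <= abs(r) + 1e-9


class TestAgreement:
    VARS = ["a", "b"]

    def test_perfect(self):
        rows = {"p1": {"a": 1.0, "b": 5.0}, "p2": {"a": 2.0, "b": 9.0}}
        out = ev.agreement(rows, rows, self.VARS)
        for r in out:
            assert r.bias == 0 and r.mae == 0 and r.mape_pct == 0
            assert r.spearman_rho == pytest.approx(1.0)
            assert r.ccc == pytest.approx(1.0)

    def test_proportional_error(self):
        truth = {f"p{i}": {"a": float(i + 1), "b": 1.0} for i in range(4)}
        pred = {k: {v: x * 1.10 for v, x in d.items()} for k, d in truth.items()}
        out = ev.agreement(pred, truth, self.VARS)
        assert out[0].mape_pct == pytest.approx(10.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        truth = {f"p{i}": {"a": rng.uniform(100, 500)} for i in range(12)}
        pred = {k: {"a": d["a"] + rng.normal(0, 20)} for k, d in truth.items()}
        (row,) = ev.agreement(pred, truth, ["a"])
        keys = sorted(truth)
        p = np.array([pred[k]["a"] for k in keys])
        t = np.array([truth[k]["a"] for k in keys])
        assert row.bias == pytest.approx((p - t).mean())
        assert row.mae == pytest.approx(np.abs(p - t).mean())
        assert row.mape_pct == pytest.approx((np.abs(p - t) / t).mean() * 100)
        assert row.ccc == pytest.approx(ev.lin_ccc(p, t))

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError, match="no paired"):
            ev.agreement({"p1": {"a": 1}}, {"p2": {"a": 1}}, ["a"])
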