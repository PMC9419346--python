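"""Agreement machinery: confusion metrics, transition pairing, CCC, MAPE.

All metrics are computed per participant-season first, then summarised as
mean (SD) across participant-seasons — never as pooled-epoch
micro-averages.  Metrics with zero denominators propagate as NaN and are
excluded from the across-season means (counts of contributing seasons are
reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import cohen_kappa_score

from chapchild.io_formats import NONSIT, SIT, EpochLabelSeries


@dataclass
class ConfusionRow:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    ppv: float
    npv: float
    kappa: float


def confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> ConfusionRow:
    """2x2 confusion metrics with SIT as the positive class.

    Zero-denominator metrics come back NaN ("missing"), never 0.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("pred/truth length mismatch")
    if len(pred) == 0:
        raise ValueError("empty label sequences")
    p = pred == SIT
    t = truth == SIT
    tp = float((p & t).sum())
    tn = float((~p & ~t).sum())
    fp = float((p & ~t).sum())
    fn = float((~p & t).sum())

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    if len(set(truth) | set(pred)) > 1:
        kappa = float(cohen_kappa_score(truth.astype(str), pred.astype(str)))
    else:
        kappa = np.nan
    return ConfusionRow(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        kappa=kappa,
    )


def extract_transitions(series: EpochLabelSeries) -> np.ndarray:
    """Sit-to-stand transition times, in seconds from series start.

    A transition is stamped at the start of the first NONSIT epoch of each
    SIT→NONSIT adjacency; stand-to-sit changes are not transitions.
    """
    lab = series.labels
    if len(lab) < 2:
        return np.empty(0)
    idx = np.flatnonzero((lab[:-1] == SIT) & (lab[1:] == NONSIT)) + 1
    return idx.astype(np.float64) * series.epoch_s


def transition_pairing(
    pred_times: np.ndarray, true_times: np.ndarray, tolerance_s: float = 60.0
) -> tuple[float, float, list[tuple[float, float]]]:
    """One-to-one pairing of predicted and true transition times.

    True transitions are processed chronologically; each is matched to the
    earliest still-unmatched predicted transition within ±tolerance_s.
    That earliest-feasible rule attains the maximum possible number of
    matches for interval-type compatibility (each true time is compatible
    with a contiguous window of predictions). Returns
    (sensitivity, ppv, matched pairs); sensitivity is NaN when there are
    no true transitions, ppv is NaN when there are no predictions.
    """
    pred = np.asarray(pred_times, dtype=np.float64)
    true = np.asarray(true_times, dtype=np.float64)
    if np.any(np.diff(pred) < 0) or np.any(np.diff(true) < 0):
        raise ValueError("transition time lists must be sorted")
    matched: list[tuple[float, float]] = []
    used = np.zeros(len(pred), dtype=bool)
    j = 0
    for t in true:
        while j < len(pred) and (used[j] or pred[j] < t - tolerance_s):
            j += 1
        if j < len(pred) and pred[j] <= t + tolerance_s:
            matched.append((float(pred[j]), float(t)))
            used[j] = True
    sens = len(matched) / len(true) if len(true) else np.nan
    ppv = len(matched) / len(pred) if len(pred) else np.nan
    return sens, ppv, matched


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean x − mean y)^2).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("lin_ccc needs paired vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom <= 0:
        raise ValueError("degenerate variance: CCC undefined")
    return float(2.0 * sxy / denom)


@dataclass
class AgreementRow:
    variable: str
    n: int
    bias: float
    bias_sd: float
    mae: float
    mape_pct: float
    spearman_rho: float
    ccc: float


def agreement(
    pred_rows: dict[str, dict],
    truth_rows: dict[str, dict],
    variables: list[str],
) -> list[AgreementRow]:
    """Participant-season agreement statistics for each variable.

    ``pred_rows``/``truth_rows`` map a participant-season key to a dict of
    variable values; only keys present in both contribute. MAPE averages
    |pred−truth|/truth over seasons with truth > 0.
    """
    keys = sorted(set(pred_rows) & set(truth_rows))
    if not keys:
        raise ValueError("no paired participant-seasons")
    out = []
    for var in variables:
        p = np.array([pred_rows[k][var] for k in keys], dtype=np.float64)
        t = np.array([truth_rows[k][var] for k in keys], dtype=np.float64)
        diff = p - t
        nz = t > 0
        mape = float(np.mean(np.abs(diff[nz]) / t[nz]) * 100.0) if nz.any() else np.nan
        rho = ccc = np.nan
        if len(keys) >= 2:
            if p.var() > 0 and t.var() > 0:
                rho = float(spearmanr(p, t).statistic)
            if (p.var() + t.var() + (p.mean() - t.mean()) ** 2) > 0:
                ccc = lin_ccc(p, t)
        out.append(
            AgreementRow(
                variable=var,
                n=len(keys),
                bias=float(diff.mean()),
                bias_sd=float(diff.std(ddof=1)) if len(keys) >= 2 else np.nan,
                mae=float(np.abs(diff).mean()),
                mape_pct=mape,
                spearman_rho=rho,
                ccc=ccc,
            )
        )
    return out


def summarize_rows(rows: list, fields: list[str]) -> dict[str, dict]:
    """Across-season mean/SD/n for each metric field, NaNs excluded."""
    out = {}
    for f in fields:
        vals = np.array([getattr(r, f) for r in rows], dtype=np.float64)
        ok = np.isfinite(vals)
        out[f] = {
            "mean": float(vals[ok].mean()) if ok.any() else np.nan,
            "sd": float(vals[ok].std(ddof=1)) if ok.sum() >= 2 else np.nan,
            "n": int(ok.sum()),
        }
    return out
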