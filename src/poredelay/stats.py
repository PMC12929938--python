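"""Evaluation metrics and dose-response statistics.

Confusion-matrix metrics (accuracy, precision, recall, F1, MCC), rank-based
ROC AUC, min-max radar scaling, MAD outlier exclusion, per-replicate baseline
correction, SEM summaries and unweighted Hill-equation fitting.

The positive class throughout is "delayed".  Ratios with a zero denominator
are reported as NaN together with a flag naming the metric — never silently
as 0 — so degenerate confusion matrices cannot inflate radar plots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import rankdata

from .errors import DataError, FitError

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "HillFit",
    "confusion",
    "compute_metrics",
    "roc_auc",
    "minmax_radar",
    "mad_filter",
    "baseline_correct",
    "summarize",
    "fit_hill",
    "hill",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.total == 0:
            raise DataError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc: float
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def confusion(labels, predictions, positive: str = "delayed") -> ConfusionCounts:
    """Exact confusion counts; labels/predictions are equal-length vectors."""
    y = list(labels)
    p = list(predictions)
    if len(y) != len(p):
        raise DataError(f"length mismatch: {len(y)} labels vs {len(p)} predictions")
    tp = fp = fn = tn = 0
    for yi, pi in zip(y, p):
        if yi == positive:
            tp += pi == positive
            fn += pi != positive
        else:
            fp += pi == positive
            tn += pi != positive
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(c: ConfusionCounts, scores=None, score_labels=None) -> MetricSet:
    """All six metrics from counts (AUC additionally needs scores + labels).

    ``scores`` must be oriented so that larger means more likely delayed.
    """
    flags: set[str] = set()
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn

    def ratio(num, den, name) -> float:
        if den == 0:
            flags.add(name)
            return math.nan
        return num / den

    accuracy = (tp + tn) / c.total
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        flags.add("f1")
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        flags.add("mcc")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(den)
    if scores is not None and score_labels is not None:
        auc = roc_auc(scores, score_labels)
    else:
        flags.add("auc")
        auc = math.nan
    return MetricSet(accuracy, precision, recall, f1, mcc, auc, flags)


def roc_auc(scores, labels, positive: str = "delayed") -> float:
    """Rank-based AUC with midrank tie handling.

    Equals the probability that a random positive outranks a random negative
    (ties counting 1/2), i.e. the trapezoidal area under the empirical ROC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive else 0 for l in labels])
    if s.size != y.size:
        raise DataError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("roc_auc requires both classes present")
    ranks = rankdata(s)  # midranks
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def minmax_radar(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-metric min-max scaling across methods/resolutions (radar-plot prep).

    Rows are classifiers, columns metrics.  Returns the scaled table and the
    list of constant columns, whose scaled values are NaN (undefined rather
    than an arbitrary 0 or 1).
    """
    if len(table) < 2:
        raise DataError("min-max scaling needs at least 2 rows")
    scaled = table.copy().astype(float)
    flagged = []
    for col in table.columns:
        v = table[col].astype(float)
        span = v.max() - v.min()
        if span == 0 or not np.isfinite(span):
            scaled[col] = np.nan
            flagged.append(col)
        else:
            scaled[col] = (v - v.min()) / span
    return scaled, flagged


def mad_filter(values) -> tuple[np.ndarray, list[int]]:
    """Exclude values deviating from the median by more than 3x the MAD.

    MAD is the raw median absolute deviation (no normal-consistency factor).
    When MAD = 0 only values equal to the median are kept, with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("mad_filter needs at least one value")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    if mad == 0.0:
        keep = np.abs(v - med) == 0.0
        if not keep.all():
            warnings.warn("MAD is zero; excluding all values not equal to the median")
    else:
        keep = np.abs(v - med) <= 3.0 * mad
    excluded = [int(i) for i in np.flatnonzero(~keep)]
    return v[keep], excluded


def baseline_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each replicate's 0 nM %%-delay from all of its rows.

    Adds a ``corrected`` column; the 0 nM rows become exactly 0.  Requires a
    0 nM measurement for every replicate.
    """
    req = {"conc_nM", "replicate", "pct_delay"}
    if not req.issubset(table.columns):
        raise DataError(f"dose table needs columns {sorted(req)}")
    out = table.copy()
    out["corrected"] = np.nan
    for rep, sub in table.groupby("replicate"):
        zero = sub.loc[sub["conc_nM"] == 0, "pct_delay"]
        if zero.empty:
            raise DataError(f"replicate {rep!r} has no 0 nM baseline row")
        out.loc[sub.index, "corrected"] = sub["pct_delay"] - float(zero.iloc[0])
    return out


def summarize(table: pd.DataFrame, value_col: str = "pct_delay") -> pd.DataFrame:
    """Per-concentration mean and SEM (sd/sqrt(n), N-1 denominator).

    A single-replicate concentration reports SEM as NaN (flagged by the
    ``n`` column), never as 0.
    """
    rows = []
    for conc, sub in table.groupby("conc_nM"):
        v = sub[value_col].to_numpy(dtype=float)
        sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan
        rows.append({"conc_nM": conc, "mean": float(v.mean()), "sem": sem, "n": v.size})
    return pd.DataFrame(rows).sort_values("conc_nM").reset_index(drop=True)


def hill(conc, vmax, ke, nh):
    """Hill curve on the baseline-corrected scale: vmax * C^nh / (ke^nh + C^nh)."""
    c = np.asarray(conc, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    out[pos] = vmax * c[pos] ** nh / (ke**nh + c[pos] ** nh)
    return out


@dataclass
class HillFit:
    nh: float
    ke_nM: float
    vmax_pct: float
    r2: float
    stderr: dict[str, float]

    def predict(self, conc):
        return hill(conc, self.vmax_pct, self.ke_nM, self.nh)


def fit_hill(conc, response) -> HillFit:
    """Unweighted nonlinear least-squares Hill fit on baseline-corrected means.

    Initialization: vmax0 = max response, ke0 = concentration nearest
    half-max, nh0 = 1; all parameters bounded positive.  Requires at least 4
    distinct concentrations including 0.
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.size != y.size:
        raise DataError("conc and response differ in length")
    uniq = np.unique(c)
    if uniq.size < 4 or 0.0 not in uniq:
        raise DataError("Hill fit needs >= 4 distinct concentrations including 0 nM")
    vmax0 = max(float(y.max()), 1e-6)
    pos = c > 0
    if not np.any(pos):
        raise DataError("Hill fit needs positive concentrations")
    ke0 = float(c[pos][np.argmin(np.abs(y[pos] - vmax0 / 2.0))])
    ke0 = max(ke0, 1e-6)
    try:
        popt, pcov = curve_fit(
            lambda cc, v, k, n: hill(cc, v, k, n),
            c,
            y,
            p0=[vmax0, ke0, 1.0],
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    vmax, ke, nh = (float(p) for p in popt)
    resid = y - hill(c, vmax, ke, nh)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    stderr = {"vmax_pct": float(perr[0]), "ke_nM": float(perr[1]), "nh": float(perr[2])}
    return HillFit(nh=nh, ke_nM=ke, vmax_pct=vmax, r2=r2, stderr=stderr)
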