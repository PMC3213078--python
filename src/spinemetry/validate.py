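"""Agreement and distribution statistics, plus phantom detection scoring.

Implements the statistics used to validate automated against manual spine
analysis — OLS regression of paired counts, the two-sample
Kolmogorov–Smirnov statistic on cumulative distributions, and per-sample
summary statistics (SD, CV = SD/mean, adjusted Fisher–Pearson skewness) —
together with ground-truth precision/recall scoring for phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult", "SummaryStats", "AgreementResult", "DetectionScore",
    "regress_counts", "ks_two_sample", "summary_stats", "score_detection",
    "agreement", "ecdf_table",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pvalue: float       # two-sided test of slope = 0
    n: int


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    cv: float           # NaN-flagged when the mean is 0
    skewness: float     # adjusted Fisher-Pearson; NaN for constant samples
    median: float
    range: float


@dataclass
class AgreementResult:
    """Manual-vs-automated comparison of one geometric parameter."""
    stats_a: SummaryStats
    stats_b: SummaryStats
    ks_d: float
    ks_p: float


@dataclass
class DetectionScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    errors: pd.DataFrame      # per matched spine: absolute geometry errors


def regress_counts(manual, auto) -> RegressionResult:
    """OLS slope (free intercept) and two-sided p-value for slope = 0."""
    x = np.asarray(manual, float)
    y = np.asarray(auto, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("manual and auto must be equal-length 1D samples")
    if len(x) < 3:
        raise ValueError("need at least 3 paired counts")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            pvalue=float(res.pvalue), n=len(x))


def ks_two_sample(a, b):
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b| and asymptotic p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def summary_stats(sample) -> SummaryStats:
    x = np.asarray(sample, float)
    if x.size < 2:
        raise ValueError("need n >= 2 for SD/CV")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = sd / mean if mean != 0 else float("nan")
    if x.size >= 3 and sd > 0:
        skw = float(stats.skew(x, bias=False))
    else:
        skw = float("nan")
    return SummaryStats(
        n=x.size, mean=mean, sd=sd, cv=cv, skewness=skw,
        median=float(np.median(x)), range=float(np.ptp(x)),
    )


def agreement(sample_a, sample_b) -> AgreementResult:
    """Distribution comparison of one parameter measured two ways."""
    d, p = ks_two_sample(sample_a, sample_b)
    return AgreementResult(
        stats_a=summary_stats(sample_a),
        stats_b=summary_stats(sample_b),
        ks_d=d, ks_p=p,
    )


def ecdf_table(sample) -> pd.DataFrame:
    """Cumulative-distribution plot data: sorted x with ECDF values."""
    x = np.sort(np.asarray(sample, float))
    return pd.DataFrame({"x": x, "ecdf": np.arange(1, x.size + 1) / x.size})


# ---------------------------------------------------------------------------
# phantom detection scoring
# ---------------------------------------------------------------------------

_GEOM = [
    ("length_um", "length"),
    ("head_width_um", "head_width"),
    ("neck_width_um", "neck_width"),
    ("head_volume_um3", "head_volume"),
]


def score_detection(records, truth: pd.DataFrame, tol: float = 0.5,
                    time: Optional[int] = None) -> DetectionScore:
    """Greedy one-to-one matching of detections to ground truth.

    ``truth`` is a phantom truth table; rows with ``present == False`` (and
    other time points, when ``time`` is given) are ignored. Matching pairs
    the globally closest attachment points first, under the tolerance
    ``tol`` (um).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    t = truth
    if "present" in t.columns:
        t = t[t["present"].astype(bool)]
    if time is not None and "time" in t.columns:
        t = t[t["time"] == time]
    t = t.reset_index(drop=True)
    det_pts = np.array([r.attachment_point for r in records], float) \
        if records else np.empty((0, 3))
    tru_pts = t[["attach_z_um", "attach_y_um", "attach_x_um"]].to_numpy(float) \
        if len(t) else np.empty((0, 3))
    pairs = []
    if len(det_pts) and len(tru_pts):
        D = np.linalg.norm(det_pts[:, None, :] - tru_pts[None, :, :], axis=2)
        cand = np.argwhere(D <= tol)
        order = np.argsort(D[cand[:, 0], cand[:, 1]])
        used_d, used_t = set(), set()
        for i, k in cand[order]:
            if i in used_d or k in used_t:
                continue
            used_d.add(int(i))
            used_t.add(int(k))
            pairs.append((int(i), int(k)))
    tp = len(pairs)
    fp = len(det_pts) - tp
    fn = len(tru_pts) - tp
    rows = []
    for i, k in pairs:
        rec = records[i]
        row = {"det_id": rec.id, "truth_id": int(t.loc[k, "spine_id"])
               if "spine_id" in t.columns else k}
        for col, attr in _GEOM:
            if col in t.columns:
                row[f"{attr}_error"] = abs(getattr(rec, attr) - t.loc[k, col])
                row[f"{attr}_true"] = t.loc[k, col]
        row["det_class"] = rec.spine_class
        if "class" in t.columns:
            row["true_class"] = t.loc[k, "class"]
        rows.append(row)
    errors = pd.DataFrame(rows)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return DetectionScore(tp=tp, fp=fp, fn=fn, precision=precision,
                          recall=recall, errors=errors)
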