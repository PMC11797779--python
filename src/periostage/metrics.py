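"""Evaluation statistics: segmentation overlap, detection mAP, error rates,
inter-rater agreement, and per-class classification metrics.

Conventions used throughout (chosen to match how these numbers are reported
in the dental-radiology literature this package targets):

* segmentation metrics are pixel-level on binary masks; IoU = TP/(TP+FP+FN),
  Dice = 2TP/(2TP+FP+FN);
* ROC-AUC is the rank-based (Mann-Whitney) statistic with ties counted 0.5;
* ICC(2,1) is the two-way random-effects, single-rater, absolute-agreement
  intraclass correlation, with the Shrout-Fleiss F-based 95% CI;
* per-class classification "accuracy" is the class recall (one-vs-rest),
  precision/recall/F1 use the 0/0 -> 0 convention;
* average precision is the area under the all-points interpolated PR curve,
  and mAP averages AP over IoU matching thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "RaterTable",
    "ClassMetrics",
    "SegMetrics",
    "IccResult",
    "seg_metrics",
    "roc_auc",
    "error_metrics",
    "icc_2_1",
    "classification_report",
    "detection_pr_map",
    "average_precision",
    "MAP_IOU_THRESHOLDS",
]

MAP_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class RaterTable:
    """n subjects x k raters of continuous measurements (no missing cells)."""

    values: np.ndarray
    rater_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x raters) array")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if k != len(self.rater_names):
            raise ValueError("rater_names length must match number of columns")
        if np.isnan(v).any():
            raise ValueError("missing cells not allowed; apply listwise deletion upstream")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SegMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    iou: float
    dice: float


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    accuracy: float
    f1: float
    support: int


@dataclass(frozen=True)
class IccResult:
    icc: float
    f_value: float
    ci95: Tuple[float, float]
    p_value: float


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def seg_metrics(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Pixel-level overlap metrics between binary masks of equal shape."""
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p = p.astype(bool)
    t = t.astype(bool)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    return SegMetrics(
        accuracy=_safe_div(tp + tn, tp + tn + fp + fn),
        precision=precision,
        recall=recall,
        f1=_safe_div(2 * precision * recall, precision + recall),
        iou=_safe_div(tp, tp + fp + fn) if (tp + fp + fn) > 0 else 1.0,
        dice=_safe_div(2 * tp, 2 * tp + fp + fn) if (tp + fp + fn) > 0 else 1.0,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, ties counted half.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def error_metrics(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """(MAE, RMSE) between two aligned measurement vectors."""
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.shape != y.shape or x.size == 0:
        raise ValueError("vectors must be non-empty and of equal length")
    d = x - y
    return float(np.mean(np.abs(d))), float(np.sqrt(np.mean(d * d)))


def icc_2_1(table: RaterTable, confidence: float = 0.95) -> IccResult:
    """ICC(2,1): two-way random effects, single rater, absolute agreement.

    From the two-way ANOVA decomposition with subjects as rows and raters
    as columns::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    F = MSR/MSE tests subject variance; the CI uses the Shrout-Fleiss
    F-based bounds with Satterthwaite degrees of freedom.
    """
    v = table.values
    n, k = v.shape
    if all(np.array_equal(v[:, 0], v[:, j]) for j in range(1, k)):
        # perfect absolute agreement: report exactly 1 (avoids the floating-
        # point cancellation in the ANOVA sums for this degenerate case)
        if np.ptp(v[:, 0]) == 0:
            warnings.warn("zero total variance; ICC defined as 1", stacklevel=2)
        return IccResult(icc=1.0, f_value=np.inf, ci95=(1.0, 1.0), p_value=0.0)
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((v - grand) ** 2)
    sse = sst - ssr - ssc
    dfr, dfc, dfe = n - 1, k - 1, (n - 1) * (k - 1)
    msr = ssr / dfr
    msc = ssc / dfc
    mse = max(sse / dfe, 0.0)
    if sst <= 1e-12:
        warnings.warn("zero total variance; ICC defined as 1", stacklevel=2)
        return IccResult(icc=1.0, f_value=np.inf, ci95=(1.0, 1.0), p_value=0.0)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 0.0
    f_value = msr / mse if mse > 0 else np.inf
    p_value = float(stats.f.sf(f_value, dfr, dfe)) if np.isfinite(f_value) else 0.0

    alpha = 1.0 - confidence
    if mse <= 0:
        ci = (1.0, 1.0)
    else:
        fj = msc / mse
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            va = (a * fj + b) ** 2
            vb = (a**2 * fj**2) / dfc + b**2 / dfe
            df_v = va / vb
            f_star = stats.f.ppf(1 - alpha / 2, dfr, df_v)
            f_lower = stats.f.ppf(1 - alpha / 2, df_v, dfr)
            lower = n * (msr - f_star * mse) / (
                f_star * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f_lower * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_lower * msr
            )
            ci = (float(max(-1.0, lower)), float(min(1.0, upper)))
        else:
            ci = (1.0, 1.0)
    return IccResult(icc=float(icc), f_value=float(f_value), ci95=ci, p_value=p_value)


def classification_report(
    truth: Sequence, predicted: Sequence, classes: Optional[Sequence] = None
) -> Dict:
    """Per-class and overall classification metrics.

    Per class (one-vs-rest): precision, recall, F1, with class "accuracy"
    reported as the recall — the convention used for per-category tables in
    the staging literature.  Overall: accuracy = fraction correct;
    precision/recall/F1 are support-weighted means of the per-class values.
    """
    y_true = list(truth)
    y_pred = list(predicted)
    if len(y_true) != len(y_pred):
        raise ValueError("truth and predicted must have the same length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred), key=str)
    else:
        unseen = set(y_pred) - set(classes)
        if unseen:
            warnings.warn(f"predicted classes not in class list: {unseen}", stacklevel=2)
            classes = list(classes) + sorted(unseen, key=str)

    per_class: Dict = {}
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        support = tp + fn
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        per_class[c] = ClassMetrics(
            precision=precision,
            recall=recall,
            accuracy=recall,
            f1=_safe_div(2 * precision * recall, precision + recall),
            support=support,
        )
    n = len(y_true)
    total_support = sum(m.support for m in per_class.values())
    weighted = lambda attr: _safe_div(
        sum(getattr(m, attr) * m.support for m in per_class.values()), total_support
    )
    overall = {
        "accuracy": _safe_div(sum(1 for t, p in zip(y_true, y_pred) if t == p), n),
        "precision": weighted("precision"),
        "recall": weighted("recall"),
        "f1": weighted("f1"),
        "support": n,
    }
    return {"per_class": per_class, "overall": overall}


# ---------------------------------------------------------------------------
# detection PR / AP
# ---------------------------------------------------------------------------


def _box_iou(a, b) -> float:
    """IoU of two (x_min, y_min, width, height) boxes."""
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix0 = max(ax0, bx0)
    iy0 = max(ay0, by0)
    ix1 = min(ax0 + aw, bx0 + bw)
    iy1 = min(ay0 + ah, by0 + bh)
    iw = max(0.0, ix1 - ix0)
    ih = max(0.0, iy1 - iy0)
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def average_precision(
    detections: Sequence[Tuple], truths: Sequence[Tuple], iou_threshold: float
) -> Tuple[float, float, float]:
    """(AP, precision, recall) at one IoU threshold.

    ``detections`` are (box, confidence) with box = (x, y, w, h);
    ``truths`` are boxes.  Greedy matching in confidence order; AP is the
    area under the monotone (all-points interpolated) PR curve; the returned
    precision/recall are at the end of the ranked list.
    """
    n_truth = len(truths)
    dets = sorted(detections, key=lambda d: -d[1])
    matched: set = set()
    tp_flags = []
    for box, _conf in dets:
        best_iou, best_j = 0.0, -1
        for j, tbox in enumerate(truths):
            if j in matched:
                continue
            iou = _box_iou(box, tbox)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched.add(best_j)
            tp_flags.append(1)
        else:
            tp_flags.append(0)
    if n_truth == 0:
        return (1.0, 1.0, 1.0) if not dets else (0.0, 0.0, 0.0)
    if not dets:
        return 0.0, 0.0, 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1 - np.asarray(tp_flags))
    prec = tp_cum / (tp_cum + fp_cum)
    rec = tp_cum / n_truth
    # all-points interpolation: precision envelope, sum over recall steps
    mprec = np.concatenate(([0.0], prec, [0.0]))
    mrec = np.concatenate(([0.0], rec, [1.0]))
    for i in range(len(mprec) - 2, -1, -1):
        mprec[i] = max(mprec[i], mprec[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    ap = float(np.sum((mrec[idx + 1] - mrec[idx]) * mprec[idx + 1]))
    return ap, float(prec[-1]), float(rec[-1])


def detection_pr_map(
    detections: Sequence[Tuple],
    truths: Sequence[Tuple],
    iou_thresholds: Sequence[float] = MAP_IOU_THRESHOLDS,
) -> Dict:
    """PR/AP per IoU threshold and their mean (mAP)."""
    per_threshold = {}
    for thr in iou_thresholds:
        ap, precision, recall = average_precision(detections, truths, thr)
        per_threshold[float(thr)] = {
            "ap": ap, "precision": precision, "recall": recall,
        }
    return {
        "per_threshold": per_threshold,
        "map": float(np.mean([d["ap"] for d in per_threshold.values()])),
    }
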