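"""Evaluation: AUROC with DeLong variance, AUPRC with bootstrap CI, the
DeLong paired test, threshold metrics, calibration and elapsed-time
stratification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps


class DegenerateLabelsError(ValueError):
    pass


def _validate(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if labels.min() == labels.max():
        raise DegenerateLabelsError("both classes must be present")
    return scores, labels


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components (V10, V01) and the AUROC point estimate."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - r_pos) / n          # per-positive components
    v01 = 1.0 - (all_r[m:] - r_neg) / m    # per-negative components
    return auc, v10, v01


@dataclass
class MetricResult:
    auroc: float
    auroc_ci: tuple[float, float]
    auprc: float
    auprc_ci: Optional[tuple[float, float]]
    precision: float
    recall: float
    f1: float
    n_pos: int
    n_neg: int


def auroc(scores, labels, alpha: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUROC (pairwise concordance, ties count 1/2) with a DeLong-variance
    normal-approximation confidence interval."""
    scores, labels = _validate(scores, labels)
    auc, v10, v01 = _delong_components(scores, labels)
    var = (
        np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0
    ) + (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    z = sps.norm.ppf(0.5 + alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(auc - half), float(auc + half))


def auprc(
    scores,
    labels,
    n_bootstrap: int = 2000,
    seed: int = 0,
    alpha: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Area under the precision-recall step curve (average precision) with
    a seeded bootstrap confidence interval."""
    scores, labels = _validate(scores, labels)
    point = _average_precision(scores, labels)
    if n_bootstrap <= 0:
        return point, (point, point)
    rng = np.random.default_rng(seed)
    n = len(scores)
    vals = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        if labels[idx].min() == labels[idx].max():
            continue
        vals.append(_average_precision(scores[idx], labels[idx]))
    lo, hi = np.percentile(vals, [(1 - alpha) / 2 * 100, (1 + alpha) / 2 * 100])
    return point, (float(lo), float(hi))


def _average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-curve area: sum over positives of precision at their rank."""
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    prec = tp / np.arange(1, len(y) + 1)
    # ties: every example within a tied score block gets the block-end precision
    distinct = np.r_[s[1:] != s[:-1], True]
    ends = np.empty(len(s), dtype=int)
    last = len(s) - 1
    for i in range(len(s) - 1, -1, -1):
        if distinct[i]:
            last = i
        ends[i] = last
    prec_at = prec[ends]
    total_pos = tp[-1]
    return float((prec_at * y).sum() / total_pos)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for the difference between two correlated
    AUROCs on paired predictions. Returns (auc_a - auc_b, p-value);
    identical score vectors give (0.0, 1.0) by convention."""
    scores_a = np.asarray(scores_a, dtype=float).ravel()
    scores_b = np.asarray(scores_b, dtype=float).ravel()
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must align")
    _, labels = _validate(scores_a, labels)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (float(diff), 0.0)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(diff), float(p)


def precision_recall_f1(
    probabilities, labels, threshold: float = 0.5
) -> tuple[float, float, float]:
    """Precision = TP/(TP+FP); Recall = TP/(TP+FN);
    F1 = 2*(P*R)/(P+R). Zero denominators yield 0 with a warning."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def safe(num, den, name):
        if den == 0:
            warnings.warn(f"zero denominator for {name}; reporting 0")
            return 0.0
        return num / den

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    f1 = safe(2 * precision * recall, precision + recall, "F1")
    return float(precision), float(recall), float(f1)


def calibration_curve(
    probabilities, labels, n_bins: int = 10
) -> list[tuple[float, float, int]]:
    """Equal-width bins on [0, 1]; returns (mean predicted, observed rate,
    count) per non-empty bin."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        out.append((float(p[sel].mean()), float(y[sel].mean()), int(sel.sum())))
    return out


def metric_result(
    scores,
    labels,
    threshold: float = 0.5,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> MetricResult:
    scores_v, labels_v = _validate(scores, labels)
    a, a_ci = auroc(scores_v, labels_v)
    ap, ap_ci = auprc(scores_v, labels_v, n_bootstrap=n_bootstrap, seed=seed)
    pr, rc, f1 = precision_recall_f1(scores_v, labels_v, threshold)
    return MetricResult(
        auroc=a,
        auroc_ci=a_ci,
        auprc=ap,
        auprc_ci=ap_ci,
        precision=pr,
        recall=rc,
        f1=f1,
        n_pos=int(labels_v.sum()),
        n_neg=int(len(labels_v) - labels_v.sum()),
    )


def metrics_by_elapsed_time(
    scores,
    labels,
    timestamps_min,
    bin_width_min: float = 30.0,
) -> list[dict]:
    """Stratified AUROC/AUPRC per elapsed-time bin plus timestamp counts.

    Bins lacking both classes are reported with ``auroc=None``."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    t = np.asarray(timestamps_min, dtype=float).ravel()
    if not (len(s) == len(y) == len(t)):
        raise ValueError("scores, labels and timestamps must align")
    out = []
    edges = np.arange(0.0, t.max() + bin_width_min, bin_width_min)
    for lo in edges:
        hi = lo + bin_width_min
        sel = (t >= lo) & (t < hi)
        if not sel.any():
            continue
        row = {"bin_start_min": float(lo), "bin_end_min": float(hi),
               "count": int(sel.sum())}
        if y[sel].min() != y[sel].max():
            row["auroc"] = auroc(s[sel], y[sel])[0]
            row["auprc"] = auprc(s[sel], y[sel], n_bootstrap=0)[0]
        else:
            row["auroc"] = None
            row["auprc"] = None
        out.append(row)
    return out
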