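"""SVG diagnostic plots: ROC, precision-recall, calibration and
elapsed-time-stratified performance."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import auroc, auprc, calibration_curve, metrics_by_elapsed_time


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    tpr = np.concatenate([[0.0], np.cumsum(y) / max(y.sum(), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(1 - y) / max((1 - y).sum(), 1)])
    return fpr, tpr


def plot_roc(scores, labels, path: str | Path) -> None:
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    fpr, tpr = _roc_points(scores, labels)
    a, _ = auroc(scores, labels)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUROC = {a:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


def plot_precision_recall(scores, labels, path: str | Path) -> None:
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / max(y.sum(), 1)
    ap, _ = auprc(scores, labels, n_bootstrap=0)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(recall, precision, label=f"AUPRC = {ap:.3f}")
    ax.axhline(y.mean(), ls="--", c="grey", lw=0.8, label="prevalence")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.legend(loc="upper right")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


def plot_calibration(probabilities, labels, path: str | Path, n_bins: int = 10) -> None:
    bins = calibration_curve(probabilities, labels, n_bins=n_bins)
    pred = [b[0] for b in bins]
    obs = [b[1] for b in bins]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(pred, obs, marker="o")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("Mean predicted probability")
    ax.set_ylabel("Observed event rate")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


def plot_elapsed_time_performance(
    scores, labels, timestamps_min, path: str | Path, bin_width_min: float = 30.0
) -> None:
    rows = metrics_by_elapsed_time(
        scores, labels, timestamps_min, bin_width_min=bin_width_min
    )
    centers = [(r["bin_start_min"] + r["bin_end_min"]) / 2 for r in rows]
    aurocs = [r["auroc"] for r in rows]
    counts = [r["count"] for r in rows]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax2 = ax.twinx()
    ax2.bar(centers, counts, width=bin_width_min * 0.85, alpha=0.25, color="grey")
    ax.plot(
        [c for c, a in zip(centers, aurocs) if a is not None],
        [a for a in aurocs if a is not None],
        marker="o",
    )
    ax.set_xlabel("Elapsed time (min)")
    ax.set_ylabel("AUROC")
    ax2.set_ylabel("Timestamp count")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
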