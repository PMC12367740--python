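"""Optional figures: ROC, reliability curves, fairness bars.

Each function draws from plain arrays or report structures (so every
figure is reproducible from the JSON reports alone) and returns the
Matplotlib axes; pass ``path`` to also save PNG/SVG.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.metrics import roc_curve

from stroketriage.evaluation import CalibrationCurve, FairnessReport


def _finish(ax, path: str | None):
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


def plot_roc(scores: Sequence[float], labels: Sequence[int], path: str | None = None, ax=None):
    """ROC curve with the chance diagonal."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    fpr, tpr, _ = roc_curve(np.asarray(labels), np.asarray(scores, dtype=float))
    ax.plot(fpr, tpr, lw=1.5)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    return _finish(ax, path)


def plot_calibration(curve: CalibrationCurve, path: str | None = None, ax=None):
    """Reliability diagram: mean predicted vs observed positive fraction."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xs = [b[2] for b in curve.bins]
    ys = [b[3] for b in curve.bins]
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.plot(xs, ys, "o-", lw=1.5)
    ax.set_xlabel("Mean predicted probability")
    ax.set_ylabel("Observed fraction of positives")
    return _finish(ax, path)


def plot_fairness(report: FairnessReport, path: str | None = None, ax=None):
    """Grouped bars of selection rate, TPR and FPR per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(report.groups) + 2, 3.5))
    x = np.arange(len(report.groups))
    width = 0.27
    for offset, (name, values) in enumerate(
        [("selection rate", report.selection_rate), ("TPR", report.tpr), ("FPR", report.fpr)]
    ):
        vals = [v if v is not None else 0.0 for v in values]
        ax.bar(x + (offset - 1) * width, vals, width, label=name)
    ax.set_xticks(x, report.groups)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return _finish(ax, path)
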