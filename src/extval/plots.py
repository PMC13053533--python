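"""Figures for validation reports: ROC curve and calibration plots.

Thin matplotlib wrappers returning the Axes so callers can compose panels
(e.g. the conventional three-panel original / intercept-updated /
fully-recalibrated calibration figure).
"""

from __future__ import annotations

import numpy as np

from . import performance

__all__ = ["plot_roc", "plot_calibration"]


def plot_roc(predictions, outcomes, ax=None, label: str | None = None):
    """ROC curve with the AUC and its DeLong 95% CI in the legend."""
    import matplotlib.pyplot as plt

    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    res = performance.auc(p, y)
    order = np.argsort(-p, kind="stable")
    tp = np.cumsum(y[order])
    fp = np.cumsum(1 - y[order])
    tpr = np.r_[0.0, tp / max(1, y.sum())]
    fpr = np.r_[0.0, fp / max(1, (1 - y).sum())]
    if ax is None:
        _, ax = plt.subplots()
    lbl = f"AUC {res.auc:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f})"
    if label:
        lbl = f"{label}: {lbl}"
    ax.plot(fpr, tpr, label=lbl)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right")
    return ax


def plot_calibration(
    predictions, outcomes, ax=None, title: str | None = None, smoother: bool = True
):
    """Decile calibration plot with binomial CIs, optional lowess overlay,
    annotated with E:O, CITL and slope."""
    import matplotlib.pyplot as plt

    cal = performance.calibrate_metrics(predictions, outcomes)
    curve = performance.calibration_curve(predictions, outcomes, "deciles")
    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        curve.predicted,
        curve.observed,
        yerr=[curve.observed - curve.ci_low, curve.ci_high - curve.observed],
        fmt="o",
        ms=4,
        capsize=2,
    )
    if smoother:
        sm = performance.calibration_curve(predictions, outcomes, "smoother")
        ax.plot(sm.predicted, sm.observed, lw=1.0)
    lim = max(float(np.max(curve.predicted)), float(np.max(curve.observed))) * 1.1
    ax.plot([0, lim], [0, lim], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("Predicted risk")
    ax.set_ylabel("Observed proportion")
    txt = f"E:O {cal.eo:.3f}\nCITL {cal.citl:.3f}\nslope {cal.slope:.3f}"
    ax.annotate(txt, xy=(0.03, 0.97), xycoords="axes fraction", va="top", fontsize=8)
    if title:
        ax.set_title(title)
    return ax
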