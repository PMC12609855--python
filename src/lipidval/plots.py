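"""Figure writers: ROC, calibration plot, and decision-curve panels.

Every figure is drawn from plain tabular inputs that the pipeline also emits
as CSV, so plots can be regenerated from the saved tables alone.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from . import performance
from .dca import DecisionCurve


def roc_figure(y, p, path, title: str = "ROC curve") -> None:
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    order = np.argsort(-p)
    y_sorted = y[order]
    tpr = np.concatenate([[0], np.cumsum(y_sorted) / max(y_sorted.sum(), 1)])
    fpr = np.concatenate([[0], np.cumsum(1 - y_sorted) / max((1 - y_sorted).sum(), 1)])
    auc = performance.auroc(y, p)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, lw=1.5, label=f"AuROC {auc.value:.2f} "
                                    f"({auc.ci_low:.2f}, {auc.ci_high:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def calibration_figure(report: performance.ValidationReport, path,
                       title: str = "Calibration plot") -> None:
    pts = report.curve.points
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="perfect calibration")
    if pts["ci_low"].notna().any():
        yerr = np.vstack([pts["observed"] - pts["ci_low"],
                          pts["ci_high"] - pts["observed"]])
        ax.errorbar(pts["predicted"], pts["observed"], yerr=yerr,
                    fmt="o", ms=4, lw=1, capsize=2, label="grouped observed")
    else:
        ax.plot(pts["predicted"], pts["observed"], lw=1.5, label="smoothed")
    lim = max(0.05, pts[["predicted", "observed"]].to_numpy().max() * 1.15)
    ax.set_xlim(0, min(1, lim))
    ax.set_ylim(0, min(1, lim))
    ax.set_xlabel("Predicted probability")
    ax.set_ylabel("Observed proportion")
    s, c = report.c_slope, report.citl
    ax.set_title(f"{title}\nC-slope {s.value:.2f} ({s.ci_low:.2f}, {s.ci_high:.2f}); "
                 f"CITL {c.value:.2f} ({c.ci_low:.2f}, {c.ci_high:.2f})",
                 fontsize=9)
    ax.legend(loc="upper left", frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def decision_curve_figure(curve: DecisionCurve, path,
                          title: str = "Decision curve analysis") -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    ax = axes[0]
    ax.plot(curve.thresholds, curve.nb_model, lw=1.5, label="model")
    ax.plot(curve.thresholds, curve.nb_all, lw=1.0, label="treat all")
    ax.axhline(0, color="k", lw=0.8, label="treat none")
    ax.set_ylim(bottom=max(-0.05, np.nanmin(curve.nb_all) * 1.1))
    ax.set_xlabel("Threshold probability")
    ax.set_ylabel("Net benefit")
    ax.legend(frameon=False, fontsize=8)
    ax = axes[1]
    ax.plot(curve.thresholds, curve.avoided_per100, lw=1.5)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("Threshold probability")
    ax.set_ylabel("Net investigations avoided per 100")
    fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
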