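"""Plot helpers for ROC curves, loss traces and embedding projections."""

from __future__ import annotations

import numpy as np

from .metrics import MetricsReport


def plot_roc(report: MetricsReport, class_name=None, ax=None):
    """ROC curve(s) with the Youden-optimal operating point marked."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    names = [class_name] if class_name else list(report.roc)
    for cname in names:
        fpr, tpr, thr = report.roc[cname]
        ax.plot(fpr, tpr, label=f"{cname} (AUC={report.auc[cname]:.3f})")
        best = report.optimal_threshold[cname]
        k = int(np.argmin(np.abs(np.where(np.isinf(thr), 1.0, thr) - best)))
        ax.plot(fpr[k], tpr[k], "o", color=ax.lines[-1].get_color())
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize="small")
    return ax


def plot_loss(trace, ax=None):
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.asarray(trace))
    ax.set_xlabel("Epoch")
    ax.set_ylabel("Training NLL")
    return ax


def plot_embedding(coords, labels, class_names=None, ax=None):
    """Scatter a 2-D projection coloured by class."""
    import matplotlib.pyplot as plt
    coords, labels = np.asarray(coords), np.asarray(labels)
    if ax is None:
        _, ax = plt.subplots()
    for lab in np.unique(labels):
        m = labels == lab
        name = class_names[lab] if class_names is not None else str(lab)
        ax.scatter(coords[m, 0], coords[m, 1], s=6, label=name)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.legend(fontsize="small", markerscale=2)
    return ax
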