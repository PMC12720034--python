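"""Plots of the stratification results (median ROC curves with CI bands)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stratify import RocSummary

__all__ = ["plot_median_roc"]


def plot_median_roc(summary: RocSummary, title: str = "", path=None):
    """Median bootstrap ROC curve with the 95% pointwise CI band."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.fill_between(summary.fpr_grid, summary.tpr_lo, summary.tpr_hi,
                    alpha=0.25, label="95% CI")
    ax.plot(summary.fpr_grid, summary.tpr_median, lw=2,
            label=f"median ROC (AUC {summary.auc_median:.2f})")
    ax.plot([0, 1], [0, 1], ls=":", c="k", lw=1, label="random")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
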