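"""Thin plotting helpers: ROC curve and relation-score heatmap exports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import ROCResult
from .scoring import ScoreMatrix

__all__ = ["plot_roc", "plot_score_heatmap"]


def plot_roc(roc: ROCResult, path: str | Path, label: str = "") -> None:
    """Write a single ROC curve with its AUC and the Youden operating point."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    name = f"{label} " if label else ""
    ax.plot(roc.fpr, roc.tpr, lw=1.5, label=f"{name}AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.plot(1.0 - roc.specificity_at_opt, roc.sensitivity_at_opt, "o", ms=5,
            label=f"threshold = {roc.optimal_threshold:.3f}")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_score_heatmap(scores: ScoreMatrix, path: str | Path) -> None:
    """Write the drugs x side-effects relation-score matrix as a heatmap."""
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(scores.score, aspect="auto", interpolation="nearest",
                   cmap="viridis")
    fig.colorbar(im, ax=ax, label="relation score")
    ax.set_xlabel("side effects")
    ax.set_ylabel("drugs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
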