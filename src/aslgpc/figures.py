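"""Plot outputs of the evaluation module.

Three figures mirror the standard read-outs of the decoding analysis:
the accuracy-versus-scan-count line plot, a panel of ROC curves, and a
per-subject strip plot of predictive probabilities (probability of the
presurgical / comparison state on the x-axis, one row per subject).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import CurveEntry, FoldPrediction, roc_auc

__all__ = ["plot_reduction_curve", "plot_roc_panel", "plot_probability_strip"]


def plot_reduction_curve(entries: Sequence[CurveEntry], path: str | Path) -> Path:
    """Balanced accuracy / sensitivity / specificity vs number of scans."""
    path = Path(path)
    sides = sorted({e.side for e in entries}, key=str)
    fig, axes = plt.subplots(1, len(sides), figsize=(5 * len(sides), 4), squeeze=False)
    for ax, side in zip(axes[0], sides):
        sub = sorted((e for e in entries if e.side == side), key=lambda e: e.n_scans)
        ns = [e.n_scans for e in sub]
        ax.plot(ns, [e.balanced_accuracy for e in sub], "o-", label="balanced accuracy")
        ax.plot(ns, [e.sensitivity for e in sub], "s--", label="sensitivity")
        ax.plot(ns, [e.specificity for e in sub], "d--", label="specificity")
        ax.axhline(0.5, color="grey", lw=0.8, ls=":")
        ax.set_xlabel("ASL scans used per session")
        ax.set_ylabel("rate")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"side: {side}" if side else "all")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_roc_panel(
    fold_sets: dict[str, Sequence[FoldPrediction]], path: str | Path
) -> Path:
    """Overlayed ROC curves, one per labelled prediction set."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for label, preds in fold_sets.items():
        fpr, tpr, auc = roc_auc(preds)
        ax.plot(fpr, tpr, label=f"{label} (AUC={auc:.2f})")
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8, ls=":")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_probability_strip(preds: Sequence[FoldPrediction], path: str | Path) -> Path:
    """Per-subject predictive probabilities of the comparison (-1) state.

    Postsurgical samples are correctly classified left of the 0.5 line,
    comparison-state samples right of it.
    """
    path = Path(path)
    preds = sorted(preds, key=lambda f: f.subject_id)
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(preds) + 1.5))
    for row, fold in enumerate(preds):
        p_comparison = 1.0 - fold.probabilities  # probability of the -1 state
        post = fold.true_labels == 1
        ax.plot(p_comparison[post], np.full(post.sum(), row), "rs", ms=5)
        ax.plot(p_comparison[~post], np.full((~post).sum(), row), "bD", ms=5)
    ax.axvline(0.5, color="black", ls="--", lw=0.8)
    ax.set_yticks(range(len(preds)))
    ax.set_yticklabels([f.subject_id for f in preds], fontsize=7)
    ax.set_xlabel("predictive probability of comparison state")
    ax.set_xlim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
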