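"""Plotting helpers: ROC curves, Kaplan-Meier curves, importance bars.

All functions draw onto a provided matplotlib Axes (or create one) and
return it, so they compose with user figures.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_roc(roc_results, ax=None):
    """Overlay one or more :class:`~treevote.classify.RocResult` curves."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if not isinstance(roc_results, (list, tuple)):
        roc_results = [roc_results]
    for r in roc_results:
        ax.plot(r.fpr, r.tpr, label=f"{r.split} (AUC = {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_km(curves: pd.DataFrame, ax=None):
    """Step plot of KM curves; expects columns time, survival[, subtype]."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if "subtype" in curves.columns:
        for k, grp in curves.groupby("subtype"):
            ax.step(grp["time"], grp["survival"], where="post", label=f"subtype {k}")
        ax.legend(fontsize=8)
    else:
        ax.step(curves["time"], curves["survival"], where="post")
    ax.set_xlabel("Time (days)")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    return ax


def plot_importance(degs: pd.DataFrame, highlight: float = 0.05, ax=None):
    """Bar plot of DEG importance scores; bars above ``highlight`` stand out."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    colors = np.where(degs["fi"] > highlight, "#e07a9b", "#86c5e8")
    ax.bar(np.arange(len(degs)), degs["fi"], color=colors)
    ax.set_xticks(np.arange(len(degs)))
    ax.set_xticklabels(degs.index, rotation=90, fontsize=6)
    ax.set_ylabel("FI$_j$")
    return ax
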