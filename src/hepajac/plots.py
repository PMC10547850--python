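"""Figure helpers: regional scatter plots, paired-correlation violins, ROC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .regional import REGIONS, cohort_regression

__all__ = ["plot_region_scatter", "plot_paired_violin", "plot_roc"]


def plot_region_scatter(rows: pd.DataFrame, path: str | Path) -> None:
    """Per-region scatter of mean volume change vs mean EQD2, points
    colored by the follow-up gap, with the cohort regression line."""
    fig, axes = plt.subplots(2, 4, figsize=(16, 7), constrained_layout=True)
    for ax, region in zip(axes.ravel(), REGIONS):
        sub = rows[rows.region == region]
        sc = ax.scatter(
            sub.mean_eqd2, sub.mean_dv_pct, c=sub.t_days, cmap="viridis", s=18
        )
        try:
            fit = cohort_regression(rows, region)
            xs = np.linspace(sub.mean_eqd2.min(), sub.mean_eqd2.max(), 2)
            ax.plot(xs, fit.slope * xs + fit.intercept, "r-", lw=1)
            ax.set_title(f"{region}  r={fit.pearson_r:.2f}")
        except ValueError:
            ax.set_title(region)
        ax.set_xlabel("mean EQD2 (Gy)")
        ax.set_ylabel("mean dv (%)")
    axes.ravel()[-1].axis("off")
    fig.colorbar(sc, ax=axes.ravel()[-1], label="days to follow-up")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_paired_violin(r_pred, r_dose, path: str | Path) -> None:
    """Distributions of per-case correlations: prediction vs dose baseline."""
    fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    ax.violinplot([np.asarray(r_dose), np.asarray(r_pred)], showmeans=True)
    ax.set_xticks([1, 2], ["-r(EQD2, map)", "r(predicted, map)"])
    ax.set_ylabel("per-case Pearson r")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_roc(scores, labels, path: str | Path, title: str = "") -> None:
    fpr, tpr, _ = roc_curve(np.asarray(labels), np.asarray(scores))
    fig, ax = plt.subplots(figsize=(4.2, 4), constrained_layout=True)
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=110)
    plt.close(fig)
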