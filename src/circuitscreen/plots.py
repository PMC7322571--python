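"""Static figure export: ensemble scatter plots and screen heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .stats import CorrelationResult


def plot_correlation_scatter(
    x: np.ndarray, y: np.ndarray, result: CorrelationResult, path: str | Path
) -> None:
    """Scatter of log2 steady-state levels with the fitted line and rho."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=6, alpha=0.4, edgecolors="none")
    xs = np.linspace(float(np.min(x)), float(np.max(x)), 50)
    ax.plot(xs, result.slope * xs + result.intercept, color="crimson", lw=1.5)
    ax.set_xlabel(f"{result.gene_x} (log2)")
    ax.set_ylabel(f"{result.gene_y} (log2)")
    ax.set_title(f"rho = {result.rho:.2f}, p = {result.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_screen_heatmap(table: pd.DataFrame, path: str | Path) -> None:
    """Cohort-by-target heatmap of screen coefficients, asterisks at q < 0.01."""
    coef = table.pivot(index="target", columns="cohort", values="coefficient")
    sig = table.pivot(index="target", columns="cohort", values="significant")
    annot = sig.map(lambda s: "*" if bool(s) else "")
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.5 * coef.shape[1] + 2), max(3.0, 0.35 * coef.shape[0] + 1))
    )
    sns.heatmap(
        coef,
        vmin=-1,
        vmax=1,
        cmap="RdBu_r",
        center=0,
        annot=annot,
        fmt="",
        cbar_kws={"label": "IRLS coefficient"},
        ax=ax,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
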