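"""Figure helpers: feature boxplots, projection scatters, metric panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import CONDITIONS
from .tda import FEATURE_NAMES

__all__ = ["feature_boxplots", "projection_scatter", "metric_boxplots"]


def feature_boxplots(features: pd.DataFrame, stats: pd.DataFrame | None = None,
                     path=None):
    """Grid of healthy-vs-MCI boxplots, one panel per feature x condition."""
    fig, axes = plt.subplots(len(FEATURE_NAMES), len(CONDITIONS),
                             figsize=(3.2 * len(CONDITIONS),
                                      2.2 * len(FEATURE_NAMES)),
                             squeeze=False)
    for i, name in enumerate(FEATURE_NAMES):
        for j, cond in enumerate(CONDITIONS):
            ax = axes[i][j]
            sub = features if cond == "ALL" else \
                features[features["condition"] == cond]
            data = [sub.loc[sub["group"] == g, name] for g in
                    ("healthy", "mci")]
            ax.boxplot(data, tick_labels=["healthy", "mci"])
            title = f"{name} [{cond}]"
            if stats is not None:
                row = stats[(stats["feature"] == name)
                            & (stats["condition"] == cond)]
                if len(row):
                    r = row.iloc[0]
                    title += (f"\np={r['p_r']:.2g} CLES={r['cles']:.2f} "
                              f"AUC={r['auc']:.2f}")
            ax.set_title(title, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def projection_scatter(projection, path=None):
    """2-D embedding coloured by group, sized by MoCA."""
    fig, ax = plt.subplots(figsize=(5, 4))
    coords = projection.coordinates
    labels = projection.labels
    groups = labels["group"] if "group" in labels else \
        pd.Series(["?"] * len(coords))
    for group, color in (("healthy", "tab:green"), ("mci", "tab:red")):
        mask = (groups == group).to_numpy()
        size = 20
        if "moca" in labels:
            size = 6 + labels.loc[mask, "moca"].to_numpy(dtype=float)
        ax.scatter(coords[mask, 0], coords[mask, 1], s=size, alpha=0.6,
                   c=color, label=group)
    ax.set_title(f"{projection.method.upper()} [{projection.condition}]")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def metric_boxplots(fold_results_by_condition: dict, metrics, path=None,
                    chance: float | None = None):
    """Per-fold metric distributions across conditions, one panel per metric."""
    fig, axes = plt.subplots(1, len(metrics),
                             figsize=(3.0 * len(metrics), 3.2), squeeze=False)
    for k, metric in enumerate(metrics):
        ax = axes[0][k]
        data, labels = [], []
        for cond, folds in fold_results_by_condition.items():
            vals = np.array([f.metrics[metric] for f in folds
                             if metric in f.metrics and
                             np.isfinite(f.metrics[metric])])
            data.append(vals)
            labels.append(cond)
        ax.boxplot(data, tick_labels=labels, whis=(2.5, 97.5))
        if chance is not None and metric == "accuracy":
            ax.axhline(chance, ls="--", c="gray", lw=1)
        ax.set_title(metric, fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
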