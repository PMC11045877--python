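"""Boxplots in the style of the quantitative figures.

Boxes span the first to third quartile with the median as a horizontal line
and whiskers extending to the most extreme points within 1.5 interquartile
ranges; each dot is one cell (or one spot for allelic analyses), colored by
replicate.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from .quantification import ExperimentTable
from .stats import GroupComparison

REPLICATE_PALETTE = ["tab:orange", "tab:blue", "tab:green"]


def boxplot_by_condition(
    table: ExperimentTable,
    value_col: str = "mean_relative_biad",
    path: str | Path | None = None,
    comparison: GroupComparison | None = None,
    ylabel: str = "relative BiAD signal",
):
    """Replicate-colored box/strip plot of per-cell values by condition."""
    df = table.to_cell_frame()
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * df["condition"].nunique(), 3.5))
    order = sorted(df["condition"].unique())
    sns.boxplot(data=df, x="condition", y=value_col, order=order,
                whis=1.5, showfliers=False, color="white", ax=ax)
    reps = sorted(df["replicate"].unique())
    palette = {r: REPLICATE_PALETTE[i % len(REPLICATE_PALETTE)]
               for i, r in enumerate(reps)}
    sns.stripplot(data=df, x="condition", y=value_col, order=order,
                  hue="replicate", palette=palette, size=3, jitter=0.2, ax=ax)
    ax.set_ylabel(ylabel)
    ax.set_xlabel("")
    if comparison is not None:
        ax.set_title(f"p = {comparison.p_value:.2e}", fontsize=9)
    ax.legend(title="replicate", fontsize=7, title_fontsize=8, loc="best")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def boxplot_groups(
    groups: dict[str, list[float]],
    path: str | Path | None = None,
    ylabel: str = "value",
):
    """Simple grouped boxplot for ad-hoc value collections (e.g. Xi vs Xa)."""
    df = pd.DataFrame(
        [(k, v) for k, vals in groups.items() for v in vals],
        columns=["group", "value"],
    )
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 3.5))
    sns.boxplot(data=df, x="group", y="value", whis=1.5, showfliers=False,
                color="white", ax=ax)
    sns.stripplot(data=df, x="group", y="value", size=3, jitter=0.2,
                  color="tab:blue", ax=ax)
    ax.set_ylabel(ylabel)
    ax.set_xlabel("")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
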