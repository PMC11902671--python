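"""Optional figure helpers: per-segment boxplots and Bland-Altman plots."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .compare import BlandAltman  # noqa: E402

__all__ = ["bland_altman_plot", "segment_boxplot"]


def bland_altman_plot(ba: BlandAltman, title: str = "", out_path=None):
    """Pairwise differences vs means with the mean and +/-1.96 SD limits."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=12, alpha=0.6)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def segment_boxplot(results: pd.DataFrame, column: str, by: str = "label",
                    title: str = "", out_path=None):
    """Boxplot of one result column grouped by segment (cohort tables)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    groups = results.dropna(subset=[column]).groupby(by)[column]
    labels = list(groups.groups)
    ax.boxplot([groups.get_group(g) for g in labels], tick_labels=labels)
    ax.set_ylabel(column)
    ax.tick_params(axis="x", rotation=75)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
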