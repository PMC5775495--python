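"""Optional figures: the (S, H) triangle and a D-statistic forest plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def triangle_plot(estimates: pd.DataFrame, path: str) -> None:
    """Scatter of ancestry S vs interclass heterozygosity H inside the
    triangle H <= 2 min(S, 1-S), colored by assigned class."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot([0, 0.5, 1, 0], [0, 1, 0, 0], color="0.6", lw=1)
    for label, grp in estimates.groupby("class"):
        ax.scatter(grp["S"], grp["H"], s=18, label=label, alpha=0.8)
    for s, h, txt in [(1, 0, "pure1"), (0, 0, "pure2"), (0.5, 1, "F1"),
                      (0.5, 0.5, "F2"), (0.75, 0.5, "BC1"), (0.25, 0.5, "BC2")]:
        ax.annotate(txt, (s, h), fontsize=7, color="0.4",
                    textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel("ancestry proportion S")
    ax.set_ylabel("interclass heterozygosity H")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.1)
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def d_forest_plot(table: pd.DataFrame, path: str, alpha: float = 0.05) -> None:
    """Forest-style plot of a D-test battery (one row per tested group)."""
    fig, ax = plt.subplots(figsize=(5, 0.5 * max(len(table), 2) + 1))
    y = np.arange(len(table))[::-1]
    sig = table["bonferroni_p"] < alpha
    ax.scatter(table["D"], y, c=np.where(sig, "tab:red", "0.5"), zorder=3)
    ax.axvline(0, color="0.7", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(table["tested_group"], fontsize=8)
    ax.set_xlabel("Patterson's D")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
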