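"""Plotting helpers: kinship heatmap and stacked ROH-sum bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def kinship_heatmap(r_matrix: pd.DataFrame, path=None):
    """Heatmap of pairwise relatedness coefficients r."""
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(r_matrix.to_numpy(), vmin=-0.1, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(r_matrix.columns)))
    ax.set_xticklabels(r_matrix.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(r_matrix.index)))
    ax.set_yticklabels(r_matrix.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="relatedness coefficient r")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def roh_stacked_bars(summary: pd.DataFrame, path=None):
    """Per-individual total ROH in the >4/>8/>12/>20 cM classes."""
    elig = summary[summary["eligible"]].sort_values("sum_gt4", ascending=False)
    x = np.arange(len(elig))
    fig, ax = plt.subplots(figsize=(9, 4))
    prev = np.zeros(len(elig))
    bands = [("sum_gt20", ">20 cM"), ("sum_gt12", "12-20 cM"),
             ("sum_gt8", "8-12 cM"), ("sum_gt4", "4-8 cM")]
    cum = np.zeros(len(elig))
    vals = {
        "sum_gt20": elig["sum_gt20"].to_numpy(),
        "sum_gt12": elig["sum_gt12"].to_numpy() - elig["sum_gt20"].to_numpy(),
        "sum_gt8": elig["sum_gt8"].to_numpy() - elig["sum_gt12"].to_numpy(),
        "sum_gt4": elig["sum_gt4"].to_numpy() - elig["sum_gt8"].to_numpy(),
    }
    for key, label in bands:
        ax.bar(x, vals[key], bottom=cum, label=label)
        cum += vals[key]
        prev = cum
    ax.set_xticks(x)
    ax.set_xticklabels(elig.index, rotation=90, fontsize=6)
    ax.set_ylabel("total ROH length (cM)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
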