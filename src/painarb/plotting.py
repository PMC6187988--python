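"""Small matplotlib helpers for the standard figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import ConditionSummary

__all__ = ["plot_performance", "plot_regime_llr"]


def plot_performance(summary: ConditionSummary, path=None):
    """Bar panels of shocks avoided, success rate and optimal-choice rate.

    Bars are grouped by goal condition with dark/light shading for low/high
    uncertainty; green lines mark the exact random-agent baselines.
    """
    table = summary.table.reset_index()
    metrics = [
        ("shocks_avoided", "shocks avoided / trial", "random_shocks_avoided"),
        ("success_rate", "success rate", "random_success_rate"),
        ("optimal", "optimal-choice proportion", None),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    x = np.arange(2)  # specific, flexible
    width = 0.35
    for ax, (col, label, baseline) in zip(axes, metrics):
        for j, unc in enumerate(("low", "high")):
            sub = table[table["uncertainty"] == unc].set_index("condition")
            vals = [sub.loc["specific", col], sub.loc["flexible", col]]
            errs = [
                sub.loc["specific", f"{col}_sem"],
                sub.loc["flexible", f"{col}_sem"],
            ]
            ax.bar(
                x + (j - 0.5) * width, vals, width, yerr=errs,
                color="0.35" if unc == "low" else "0.7", label=f"{unc} uncertainty",
            )
            if baseline is not None:
                base = [sub.loc["specific", baseline], sub.loc["flexible", baseline]]
                for xi, b in zip(x + (j - 0.5) * width, base):
                    ax.hlines(b, xi - width / 2, xi + width / 2, color="green", lw=1.5)
        if col == "optimal":
            ax.axhline(0.25, color="green", lw=1.0, ls=":")
        ax.set_xticks(x, ["specific", "flexible"])
        ax.set_ylabel(label)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_regime_llr(group_table: pd.DataFrame, path=None):
    """Bar plot of the MB-minus-MF statistic per arbitration regime."""
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    regimes = ["mf", "mb"]
    vals = [group_table.loc[r, "mean_subject_statistic"] for r in regimes]
    ax.bar(
        [0, 1], vals, 0.6, color=["0.6", "0.3"],
    )
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks([0, 1], ["$p_{MB}<0.5$", "$p_{MB}>0.5$"])
    ax.set_ylabel("log-likelihood (MB − MF)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
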