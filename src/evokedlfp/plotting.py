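"""Plots for contrast results: per-stratum summaries and estimation plots."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_contrast_summary", "estimation_plot"]


def plot_contrast_summary(contrasts: pd.DataFrame, path) -> None:
    """Point estimate + CI per band, one panel per (age, time bin).

    Mirrors the usual estimation-statistics layout: paired mean differences
    as dots, vertical bars spanning the bootstrap confidence interval, a
    dashed zero line for reference.
    """
    ages = sorted(contrasts["age_group"].unique())
    bins = sorted(contrasts[["bin_start_ms", "bin_end_ms"]].drop_duplicates().itertuples(index=False))
    fig, axes = plt.subplots(
        len(ages), len(bins), figsize=(3.2 * len(bins), 2.6 * len(ages)),
        squeeze=False, sharey="row",
    )
    for i, age in enumerate(ages):
        for j, (b0, b1) in enumerate(bins):
            ax = axes[i][j]
            sub = contrasts[
                (contrasts["age_group"] == age) & (contrasts["bin_start_ms"] == b0)
            ].reset_index(drop=True)
            x = np.arange(len(sub))
            ax.axhline(0.0, color="0.6", lw=0.8, ls="--")
            ax.errorbar(
                x,
                sub["mean_diff"],
                yerr=[sub["mean_diff"] - sub["ci_low"], sub["ci_high"] - sub["mean_diff"]],
                fmt="o",
                color="C0",
                capsize=3,
            )
            ax.set_xticks(x, sub["band"], rotation=45)
            ax.set_title(f"{age}  {b0:.0f}-{b1:.0f} ms", fontsize=9)
            if j == 0:
                ax.set_ylabel("paired mean diff.\n(normalized energy)")
    name = contrasts["contrast"].iloc[0] if len(contrasts) else "contrast"
    fig.suptitle(name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def estimation_plot(result, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Gardner–Altman-style panel for one paired contrast.

    Shows the bootstrap sampling distribution of the paired mean difference
    with the point estimate and the BCa interval.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3.5))
    dist = np.asarray(result.bootstrap_distribution)
    ax.hist(dist, bins=60, orientation="horizontal", color="0.75", density=True)
    ax.axhline(0.0, color="0.5", lw=0.8, ls="--")
    ax.plot([0], [result.mean_diff], "ko", ms=7)
    ax.vlines(0, result.ci_low, result.ci_high, color="k", lw=2)
    ax.set_ylabel("paired mean difference")
    ax.set_xticks([])
    label = " vs ".join(reversed(list(result.labels)))
    ax.set_title(f"{label}\np_perm = {result.p_perm:.3g}", fontsize=9)
    return ax
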