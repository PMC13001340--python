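"""Optional plot rendering (Manhattan scan, mean log-histograms)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_manhattan(table: pd.DataFrame, consensus: str = "chrHis", ax=None):
    """Scatter of bin signal vs cumulative genome coordinate.

    Chromosomes alternate grey shades; consensus bins are drawn in red (the
    collapsed repeat unit sits at the far right by construction).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    chroms = list(dict.fromkeys(table["chrom"]))
    for i, chrom in enumerate(chroms):
        sub = table[table["chrom"] == chrom]
        color = "tab:red" if chrom == consensus else ("0.45" if i % 2 else "0.7")
        ax.scatter(sub["cum_pos"], sub["signal"], s=6, color=color, label=chrom if chrom == consensus else None)
    for row in table[table["label"] != ""].itertuples():
        ax.annotate(row.label, (row.cum_pos, row.signal), fontsize=6)
    ax.set_xlabel("cumulative genome position (bp)")
    ax.set_ylabel("summed signal per bin")
    return ax


def plot_mean_log_histogram(curves: dict[str, pd.DataFrame], ax=None):
    """Mean log10(count+1) curves per genotype with SEM bands.

    ``curves`` maps genotype to the output of
    :func:`hlbquant.fish.mean_log_histogram`; the dashed vertical line marks
    each group's mean 90th-percentile bin.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for genotype, df in curves.items():
        line, = ax.plot(df["bin"], df["log10_mean"], label=genotype)
        lo = np.log10(np.clip(df["mean_count"] - df["sem"], 0, None) + 1.0)
        hi = np.log10(df["mean_count"] + df["sem"] + 1.0)
        ax.fill_between(df["bin"], lo, hi, alpha=0.3, color=line.get_color())
        if "pct90_mean" in df.attrs:
            ax.axvline(df.attrs["pct90_mean"], linestyle="--", color=line.get_color(), linewidth=0.8)
    ax.set_xlabel("pixel intensity bin")
    ax.set_ylabel("log10(mean count + 1)")
    ax.legend()
    return ax
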