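"""Optional matplotlib rendering of the statistics outputs.

Cosmetic only: box plots of expanded viability distributions, binned
viability curves, and a stacked-bar seed-composition "logo".  Nothing in
the analysis depends on these.
"""

from __future__ import annotations

from os import PathLike
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .viabstats import NUCLEOTIDES, BoxStats

_NT_COLORS = {"A": "#33a02c", "C": "#1f78b4", "G": "#e31a1c", "U": "#ff7f00"}


def plot_box(stats_by_group: Mapping[str, BoxStats], path: str | PathLike) -> None:
    """Box-and-whisker plot from precomputed BoxStats (no raw data needed)."""
    fig, ax = plt.subplots(figsize=(1.5 + len(stats_by_group), 4))
    boxes = [
        {
            "label": name,
            "med": bs.median,
            "q1": bs.q1,
            "q3": bs.q3,
            "whislo": bs.whisker_low,
            "whishi": bs.whisker_high,
            "fliers": list(bs.outliers),
        }
        for name, bs in stats_by_group.items()
    ]
    ax.bxp(boxes, showfliers=True)
    ax.set_ylabel("6mer seed viability (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_curve(curve: pd.DataFrame, path: str | PathLike) -> None:
    """Binned viability curve; one line per group, raw per-bin weights."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in curve.groupby("group"):
        ax.plot(sub["bin_left"], sub["weight"], label=str(group), drawstyle="steps-post")
    ax.set_xlabel("6mer seed viability (%)")
    ax.set_ylabel("aggregated read counts")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_logo(composition: pd.DataFrame, path: str | PathLike) -> None:
    """Stacked-bar nucleotide frequencies at seed positions 1-6."""
    fig, ax = plt.subplots(figsize=(4, 3))
    bottom = None
    x = range(1, 7)
    for nt in NUCLEOTIDES:
        heights = composition.loc[nt].to_numpy()
        ax.bar(x, heights, bottom=bottom, color=_NT_COLORS[nt], label=nt)
        bottom = heights if bottom is None else bottom + heights
    ax.set_xlabel("seed position")
    ax.set_ylabel("frequency")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
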