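"""Bar-profile and senescence-curve plots."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_divergence_bars(
    calls: Sequence,
    path: str | Path,
    truncation_line: Optional[int] = 125,
    title: str = "",
) -> None:
    """Per-telomere bar plot: black undiverged segment, light-gray diverged
    segment, one bar per clone sorted by undiverged length; optional red
    line at the truncation threshold."""
    calls = sorted(calls, key=lambda c: (-c.undiverged_length_nt, c.clone_id))
    x = range(len(calls))
    undiv = [c.undiverged_length_nt for c in calls]
    div = [max(0, c.clone_length_nt - c.undiverged_length_nt) for c in calls]
    fig, ax = plt.subplots(figsize=(max(4, len(calls) * 0.18), 4))
    ax.bar(x, undiv, width=0.85, color="black")
    ax.bar(x, div, width=0.85, bottom=undiv, color="lightgray")
    if truncation_line is not None:
        ax.axhline(truncation_line, color="red", linewidth=1)
    ax.set_ylabel("telomere length (nt)")
    ax.set_xlabel("clones (sorted by undiverged length)")
    ax.set_xticks([])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_senescence(summaries: Sequence, path: str | Path, title: str = "") -> None:
    """Mean density vs mean cumulative PD per genotype, with SE bars."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for summ in summaries:
        t = summ.table
        ax.errorbar(
            t["mean_cumulative_pd"],
            t["mean_density"],
            xerr=t["se_cumulative_pd"],
            yerr=t["se_density"],
            marker="o",
            markersize=3,
            capsize=2,
            label=f"{summ.genotype} (n={summ.n_replicates})",
        )
    ax.set_yscale("log")
    ax.set_xlabel("cumulative population doublings")
    ax.set_ylabel("cell density (cells/ml)")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
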