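"""SEM plot: per-letter log2 effect series across motif positions."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import ALPHABET, SEMResult

# C/M and G/W share a hue (solid vs dashed-marker pairing)
LETTER_COLORS = {
    "A": "#2ca02c",
    "C": "#1f77b4",
    "G": "#ff7f0e",
    "T": "#d62728",
    "M": "#17becf",
    "W": "#ffbf00",
}


def render_plot(sem: SEMResult, path: str, title: str = "SNP effect matrix") -> None:
    """Render the SEM as a vector plot.

    Six per-letter series over motif positions 1..L with stderr error bars
    (converted to log2 via the delta method), a solid line at 0 (endogenous
    baseline) and a dashed gray line at the scrambled baseline. NaN cells
    leave gaps. A failing QC statistic flags the plot in red.
    """
    L = sem.length
    x = np.arange(1, L + 1)
    fig, ax = plt.subplots(figsize=(max(6, L * 0.8), 4.5))
    ln2 = np.log(2.0)
    for j, letter in enumerate(ALPHABET):
        y = sem.scores[:, j]
        if np.all(np.isnan(y)):
            continue
        raw = sem.endogenous_baseline * np.exp2(y)
        with np.errstate(invalid="ignore", divide="ignore"):
            yerr = sem.stderr[:, j] / (raw * ln2)
        yerr = np.where(np.isfinite(yerr), yerr, 0.0)
        ax.errorbar(
            x,
            y,
            yerr=yerr,
            label=letter,
            color=LETTER_COLORS[letter],
            marker="o" if letter in "ACGT" else "s",
            linestyle="-" if letter in "ACGT" else "--",
            capsize=2,
            markersize=4,
        )
    ax.axhline(0.0, color="0.3", linewidth=1.2)
    ax.axhline(sem.scrambled_baseline, color="0.6", linewidth=1.2, linestyle="--")
    ax.set_xticks(x)
    ax.set_xlabel("motif position")
    ax.set_ylabel("log2 effect vs endogenous baseline")
    failed = sem.qc_pass is False
    if failed:
        title = f"{title} — QC FAIL ({sem.qc_statistic:.2f} < {sem.qc_threshold:g})"
    ax.set_title(title, color="red" if failed else "black")
    if failed:
        for spine in ax.spines.values():
            spine.set_edgecolor("red")
            spine.set_linewidth(2)
    ax.legend(ncol=6, fontsize=8, loc="lower center")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
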