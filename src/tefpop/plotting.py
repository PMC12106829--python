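"""Plot helpers: LD decay curves and binned Manhattan-style panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .genotypes import LdDecayResult  # noqa: E402


def plot_ld_decay(decay: LdDecayResult, ax=None):
    """Binned mean r^2 against distance, with the decay threshold marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(decay.bin_mid_bp, decay.mean_r2, marker="o", ms=3, lw=1)
    ax.axhline(decay.threshold, ls="--", color="grey",
               label=f"r² = {decay.threshold}")
    if decay.reached:
        ax.axvline(decay.decay_bp, ls=":", color="firebrick",
                   label=f"decay = {decay.decay_bp:,.0f} bp")
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel("mean r²")
    ax.legend(frameon=False)
    return ax


def plot_binned_manhattan(binned: pd.DataFrame, threshold_score: float | None = None,
                          ax=None):
    """Per-bin significant k-mer counts along the genome (one colour per
    chromosome); input is the long per-bin table from ``gwas.bin_scores``."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    offset = 0
    ticks, labels = [], []
    for chrom in sorted(binned["chrom"].unique()):
        sub = (binned[binned["chrom"] == chrom]
               .groupby("bin_start", as_index=False)["count"].sum())
        ax.vlines(sub["bin_start"] + offset, 0, sub["count"], lw=2)
        ticks.append(offset + sub["bin_start"].max() / 2)
        labels.append(chrom)
        offset += sub["bin_start"].max() + 20_000
    ax.set_xticks(ticks, labels)
    ax.set_ylabel("significant k-mers / bin")
    if threshold_score is not None:
        ax.set_title(f"score threshold {threshold_score:.2f}")
    return ax
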