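"""Genome-scan plot: windowed delta(SNP-index) with null band overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .nullband import NullCITable, lookup_ci


def plot_delta_scan(windows, table: NullCITable, level: float,
                    regions=None, path="delta_scan.png") -> None:
    """One panel per chromosome: mean delta vs midpoint, band in red."""
    chroms = sorted(windows["chrom"].unique())
    fig, axes = plt.subplots(len(chroms), 1,
                             figsize=(9, 1.8 * len(chroms)),
                             sharey=True, squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        grp = windows[windows["chrom"] == chrom]
        x = grp["midpoint"] / 1e6
        bands = [lookup_ci(table, d, level) for d in grp["mean_depth"]]
        lo = [b[0] for b in bands]
        up = [b[1] for b in bands]
        ax.plot(x, grp["mean_delta"], lw=0.8, color="black")
        ax.plot(x, lo, lw=0.6, color="red")
        ax.plot(x, up, lw=0.6, color="red")
        ax.axhline(0, lw=0.4, color="grey")
        for r in regions or []:
            if r.chrom == chrom:
                ax.axvspan(r.start / 1e6, r.end / 1e6, alpha=0.2,
                           color="orange")
        ax.set_ylabel(chrom, fontsize=8)
        ax.set_ylim(-1.05, 1.05)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.suptitle(f"delta(SNP-index) scan, P<{1 - level:g} band")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
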