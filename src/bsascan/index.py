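"""SNP-index, delta(SNP-index) and sliding-window smoothing.

The SNP-index of a bulk at a site is the fraction of its reads carrying
the non-reference (mutant) allele: 0 when every read matches the
reference, 1 when every read carries the mutant allele.  delta(SNP-index)
subtracts the low (light, QL) bulk's index from the high (dark, SL)
bulk's, so a locus fully linked to the selected trait approaches +1 with
this polarity and an unlinked locus stays near 0.

Windows are 1-based closed intervals anchored at coordinate 1, advancing
by ``step``; each emitted window averages its member sites with an
unweighted mean and empty windows are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import BulkCounts

#: Columns of the window table produced by :func:`sliding_window`.
WINDOW_COLUMNS = [
    "chrom", "start", "end", "midpoint", "n_snps",
    "mean_index_high", "mean_index_low", "mean_delta", "mean_depth",
]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry (defaults: 1-Mb window, 10-kb increment)."""

    window_size: int = 1_000_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0:
            raise ValueError("window_size and step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")


def snp_index(counts: BulkCounts) -> float:
    """Fraction of reads carrying the mutant allele at one site.

    Raises ValueError at zero depth: upstream depth filtering must have
    removed such sites.
    """
    depth = counts.ref_count + counts.alt_count
    if depth == 0:
        raise ValueError("SNP-index undefined at zero read depth")
    return counts.alt_count / depth


def delta_snp_index(index_high: float, index_low: float) -> float:
    """High-bulk SNP-index minus low-bulk SNP-index, in [-1, 1]."""
    return index_high - index_low


def compute_indices(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site SNP-index of each bulk and their difference.

    Input is a canonical site table (both bulk depths >= 1, i.e. already
    depth-filtered).  Returns a DataFrame with columns chrom, pos,
    index_high, index_low, delta, depth_high, depth_low, in input order.
    """
    depth_high = (sites["high_ref"] + sites["high_alt"]).to_numpy()
    depth_low = (sites["low_ref"] + sites["low_alt"]).to_numpy()
    bad = np.flatnonzero((depth_high == 0) | (depth_low == 0))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"zero-depth bulk at {sites['chrom'].iat[i]}:{sites['pos'].iat[i]}"
            " — filter sites before computing indices")
    index_high = sites["high_alt"].to_numpy() / depth_high
    index_low = sites["low_alt"].to_numpy() / depth_low
    return pd.DataFrame({
        "chrom": sites["chrom"].to_numpy(),
        "pos": sites["pos"].to_numpy(),
        "index_high": index_high,
        "index_low": index_low,
        "delta": index_high - index_low,
        "depth_high": depth_high,
        "depth_low": depth_low,
    })


def sliding_window(records: pd.DataFrame, cfg: WindowConfig,
                   chrom_lengths: dict) -> pd.DataFrame:
    """Average per-site indices in sliding windows along each chromosome.

    Windows start at 1, 1+step, 1+2*step, ... while the start lies on the
    chromosome; a site at ``pos`` belongs to every window
    ``[start, start + window_size - 1]`` (1-based closed) containing it.
    ``midpoint`` (start + window_size/2, clipped to the chromosome end) is
    the plotting coordinate.  ``mean_depth`` is the mean over member sites
    of (depth_high + depth_low)/2, the representative depth used for
    confidence-band lookup.

    Raises on unsorted input or on a chromosome missing from
    ``chrom_lengths``.
    """
    out = []
    for chrom, grp in records.groupby("chrom", sort=True):
        if chrom not in chrom_lengths:
            raise KeyError(f"chromosome {chrom!r} not in chrom_lengths")
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"records not sorted by position on {chrom}")
        length = int(chrom_lengths[chrom])

        starts = np.arange(1, length + 1, cfg.step, dtype=np.int64)
        ends = starts + cfg.window_size - 1
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        keep = n > 0

        # prefix sums turn each window mean into two lookups
        def window_means(values: np.ndarray) -> np.ndarray:
            csum = np.concatenate(([0.0], np.cumsum(values)))
            return (csum[hi[keep]] - csum[lo[keep]]) / n[keep]

        mean_high = window_means(grp["index_high"].to_numpy())
        mean_low = window_means(grp["index_low"].to_numpy())
        mean_delta = window_means(grp["delta"].to_numpy())
        site_depth = (grp["depth_high"].to_numpy()
                      + grp["depth_low"].to_numpy()) / 2.0
        mean_depth = window_means(site_depth)

        midpoint = np.minimum(starts[keep] + cfg.window_size // 2, length)
        out.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts[keep],
            "end": ends[keep],
            "midpoint": midpoint,
            "n_snps": n[keep],
            "mean_index_high": mean_high,
            "mean_index_low": mean_low,
            "mean_delta": mean_delta,
            "mean_depth": mean_depth,
        }))
    if not out:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            WINDOW_COLUMNS,
            [str, np.int64, np.int64, np.int64, np.int64,
             float, float, float, float])})
    return pd.concat(out, ignore_index=True)


def write_window_table(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False)


def windows_to_bed(windows: pd.DataFrame, path) -> None:
    """Export windows as BED (0-based half-open: start-1, end)."""
    bed = pd.DataFrame({
        "chrom": windows["chrom"],
        "start": windows["start"] - 1,
        "end": windows["end"],
        "name": [f"win{i}" for i in range(len(windows))],
        "score": windows["mean_delta"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
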