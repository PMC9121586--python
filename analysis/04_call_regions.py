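#!/usr/bin/env python
"""Call candidate QTL regions against the null confidence bands.

Compares each window's mean delta(SNP-index) with the simulated null
band at the window's mean depth, merges overlapping same-signed
significant windows into regions at both P<0.05 and P<0.01, and checks
the calls against the simulator's ground truth.

Writes results/regions.tsv, results/regions.bed and
results/delta_scan.png.

Usage: python analysis/04_call_regions.py
"""

import argparse
from pathlib import Path

import pandas as pd

from bsascan.nullband import NullCITable
from bsascan.plotting import plot_delta_scan
from bsascan.regions import (call_candidate_regions, regions_to_frame,
                             write_regions_bed)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--windows", default="results/windows.tsv")
    ap.add_argument("--ci-table", default="results/ci_table.tsv")
    ap.add_argument("--truth", default="results/sim/truth.tsv")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    windows = pd.read_csv(args.windows, sep="\t")
    table = NullCITable.from_tsv(args.ci_table)
    outdir = Path(args.outdir)

    with open(args.truth) as fh:
        kv = dict(tok.split("=") for tok in
                  fh.readline().lstrip("# ").split())
    qtl_chrom, qtl_pos = kv["qtl_chrom"], int(kv["qtl_pos"])

    for level in (0.95, 0.99):
        regions = call_candidate_regions(windows, table, level)
        tag = f"P<{1 - level:g}"
        print(f"{tag}: {len(regions)} candidate region(s)")
        for r in regions:
            span_mb = (r.end - r.start) / 1e6
            inside = r.contains(qtl_chrom, qtl_pos)
            print(f"  {r.chrom}:{r.start:,}-{r.end:,} ({span_mb:.2f} Mb), "
                  f"peak delta {r.peak_delta:+.3f}, {r.n_windows} windows"
                  f"{'  <- contains the planted QTL' if inside else ''}")
        if level == 0.99:
            regions_to_frame(regions).to_csv(
                outdir / "regions.tsv", sep="\t", index=False)
            write_regions_bed(regions, outdir / "regions.bed")
            plot_delta_scan(windows, table, level, regions,
                            outdir / "delta_scan.png")
    print(f"planted QTL truth: {qtl_chrom}:{qtl_pos:,}")
    print(f"wrote {outdir}/regions.tsv, regions.bed, delta_scan.png")


if __name__ == "__main__":
    main()
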