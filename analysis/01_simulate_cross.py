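#!/usr/bin/env python
"""Simulate the bulked-segregant F2 experiment.

Crosses two inbred parents fixed for opposite alleles at every marker,
selfs the F1 to get 278 F2 individuals, scores a liability phenotype
driven by one incompletely dominant QTL, selects the 20 darkest and 20
lightest individuals into two bulks and sequences each bulk at ~20x.

Writes results/sim/: pools.vcf (two-sample VCF), truth.tsv (ground
truth), phenogeno.tsv (phenotype + thinned genotypes for the marker
scan).

Usage: python analysis/01_simulate_cross.py [--seed 1]
"""

import argparse

import numpy as np

from bsascan.pipeline import run_simulate
from bsascan.simulate import F2SimParams


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/sim")
    args = ap.parse_args()

    params = F2SimParams(seed=args.seed)
    paths = run_simulate(params, args.outdir)

    from bsascan.simulate import simulate_experiment
    exp = simulate_experiment(params)
    dosage = exp.truth.qtl_dosage
    counts = np.bincount(dosage, minlength=3)
    print(f"simulated F2 of {params.n_f2} individuals on "
          f"{len(params.chrom_lengths)} chromosomes, "
          f"{len(exp.sites):,} parental SNPs")
    print(f"QTL at {params.qtl_chrom}:{params.qtl_pos:,} "
          f"(a={params.additive_effect}, d={params.dominance_effect}, "
          f"residual sd={params.residual_sd})")
    print(f"QTL dosage counts (light-hom : het : dark-hom) = "
          f"{counts[0]} : {counts[1]} : {counts[2]}  (expect ~1:2:1)")
    hi, lo = exp.truth.high_idx, exp.truth.low_idx
    print(f"dark bulk mean QTL dosage  {dosage[hi].mean():.2f} "
          f"(20 individuals, extreme dark tail)")
    print(f"light bulk mean QTL dosage {dosage[lo].mean():.2f} "
          f"(20 individuals, extreme light tail)")
    for k, v in paths.items():
        print(f"wrote {k}: {v}")


if __name__ == "__main__":
    main()
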