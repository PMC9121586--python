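"""Forward simulation of a bulked-segregant F2 sequencing experiment.

The generator emulates the study design the scan is built for: two inbred
parents fixed for opposite alleles at every marker (a light- and a
dark-pericarp line), an F1 selfed to give an F2 population, a single
incompletely dominant major QTL acting on a continuous liability score,
extreme-tail selection of ``pool_size`` individuals into each of two
bulks, and pooled short-read sequencing of the bulks at a mean depth of
~20x with a small per-read allele error.

Meiosis is modelled as a crossover process with a uniform recombination
rate (``cm_per_mb``), Poisson crossover counts, uniform breakpoints and
no interference, so two markers at genetic distance d Morgans recombine
with Haldane's frequency r = (1 - exp(-2d)) / 2.

The reference genome is identified with the light parent, so the "mutant"
allele is the dark-parent allele and delta(SNP-index) at a linked locus
is driven toward +1 (a ``polarity`` flag flips this for the case where
the reference is a third line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import SITE_COLUMNS, write_pooled_vcf

_DEFAULT_CHROMS = {f"chr{i}": 30_000_000 for i in range(1, 8)}


@dataclass(frozen=True)
class F2SimParams:
    """Parameters of the synthetic F2 BSA-seq experiment.

    Defaults describe the emulated design: 7 chromosomes of 30 Mb (a
    cucumber-like 2n = 2x = 14 karyotype), one parental SNP every ~2 kb,
    3.3 cM/Mb, 278 F2 individuals, a single QTL on chr3 with additive
    effect ``additive_effect`` and dominance ``dominance_effect`` (0.6 x
    additive: the heterozygote leans toward the dark parent), bulks of 20,
    ~20x pooled depth, 0.1% per-read allele error.
    """

    chrom_lengths: dict = field(
        default_factory=lambda: dict(_DEFAULT_CHROMS))
    snp_spacing: int = 2_000
    cm_per_mb: float = 3.3
    n_f2: int = 278
    qtl_chrom: str = "chr3"
    qtl_pos: int = 21_000_000
    additive_effect: float = 1.0
    dominance_effect: float = 0.6
    residual_sd: float = 1.0
    pool_size: int = 20
    depth_mean: float = 20.0
    seq_error: float = 0.001
    polarity: int = 1          # +1: mutant allele = dark parent
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths or \
                min(self.chrom_lengths.values()) <= 0:
            raise ValueError("chrom_lengths must be positive")
        if min(self.snp_spacing, self.n_f2, self.pool_size) <= 0:
            raise ValueError("sizes must be positive")
        if self.qtl_chrom not in self.chrom_lengths:
            raise ValueError(f"qtl_chrom {self.qtl_chrom!r} unknown")
        if not 1 <= self.qtl_pos <= self.chrom_lengths[self.qtl_chrom]:
            raise ValueError("qtl_pos outside its chromosome")
        if not 0.0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.residual_sd < 0 or self.depth_mean <= 0:
            raise ValueError("residual_sd >= 0 and depth_mean > 0 required")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.n_f2 < 2 * self.pool_size:
            raise ValueError("n_f2 must be >= 2 * pool_size")


@dataclass
class F2Truth:
    """Simulator ground truth for recovery tests."""

    qtl_chrom: str
    qtl_pos: int
    qtl_snp_index: int            # row of the causal SNP in the SNP table
    qtl_dosage: np.ndarray        # per-individual dark-allele dosage at QTL
    phenotypes: np.ndarray
    high_idx: np.ndarray | None = None   # dark-bulk member indices
    low_idx: np.ndarray | None = None    # light-bulk member indices


@dataclass
class F2Population:
    """A simulated F2 population: SNP map, genotypes, phenotypes, truth."""

    params: F2SimParams
    snps: pd.DataFrame            # chrom, pos, ref, alt (sorted)
    genotypes: np.ndarray         # (n_f2, n_snps) dark-allele dosage int8
    phenotypes: np.ndarray        # (n_f2,)
    truth: F2Truth


def simulate_gametes(positions: np.ndarray, length_bp: int,
                     cm_per_mb: float, n_gametes: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Parental origin (0/1) of ``n_gametes`` gametes at marker positions.

    Crossover count per gamete ~ Poisson(genetic length in Morgans),
    breakpoints uniform on the chromosome, starting phase equiprobable.
    """
    morgans = length_bp * cm_per_mb / 1e8
    out = np.empty((n_gametes, positions.size), dtype=np.int8)
    n_xo = rng.poisson(morgans, size=n_gametes)
    phases = rng.integers(0, 2, size=n_gametes)
    for g in range(n_gametes):
        if n_xo[g]:
            breaks = np.sort(rng.uniform(0, length_bp, size=n_xo[g]))
            out[g] = (phases[g] + np.searchsorted(breaks, positions)) % 2
        else:
            out[g] = phases[g]
    return out


def _snp_positions(rng: np.random.Generator, length: int, spacing: int,
                   must_include: int | None = None) -> np.ndarray:
    """Marker coordinates with ~exponential gaps of the given mean."""
    n_guess = int(length / spacing * 1.5) + 16
    pos = np.cumsum(rng.exponential(spacing, size=n_guess))
    while pos[-1] < length:
        pos = np.concatenate(
            [pos, pos[-1] + np.cumsum(rng.exponential(spacing, size=n_guess))])
    pos = np.unique(pos[pos < length].astype(np.int64) + 1)
    if must_include is not None:
        pos = np.unique(np.concatenate([pos, [must_include]]))
    return pos


def simulate_f2_population(params: F2SimParams,
                           rng: np.random.Generator | None = None
                           ) -> F2Population:
    """Simulate genotypes and phenotypes of an F2 population.

    Genotypes are dark-parent allele dosages in {0, 1, 2}; at any single
    marker they segregate 1:2:1.  The phenotype is the liability score
    a*(dosage-1) + d*[dosage==1] + Normal(0, residual_sd) evaluated at the
    causal SNP (which is always present in the marker set, at
    ``qtl_pos``).  Deterministic given ``params.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))

    chunks, snp_frames = [], []
    for chrom in sorted(params.chrom_lengths):
        length = int(params.chrom_lengths[chrom])
        include = params.qtl_pos if chrom == params.qtl_chrom else None
        pos = _snp_positions(rng, length, params.snp_spacing, include)
        gametes = simulate_gametes(pos, length, params.cm_per_mb,
                                   2 * params.n_f2, rng)
        chunks.append(gametes[0::2] + gametes[1::2])
        refs = rng.choice(list("ACGT"), size=pos.size)
        shift = rng.integers(1, 4, size=pos.size)
        alts = np.array(list("ACGT"))[
            (np.searchsorted(np.array(list("ACGT")), refs) + shift) % 4]
        snp_frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos, "ref": refs, "alt": alts}))

    snps = pd.concat(snp_frames, ignore_index=True)
    genotypes = np.concatenate(chunks, axis=1)

    qtl_snp_index = int(np.flatnonzero(
        (snps["chrom"] == params.qtl_chrom).to_numpy()
        & (snps["pos"] == params.qtl_pos).to_numpy())[0])
    dosage = genotypes[:, qtl_snp_index].astype(float)

    a, d = params.additive_effect, params.dominance_effect
    noise = rng.normal(0.0, 1.0, size=params.n_f2) * params.residual_sd
    phenotypes = a * (dosage - 1.0) + d * (dosage == 1.0) + noise

    truth = F2Truth(qtl_chrom=params.qtl_chrom, qtl_pos=params.qtl_pos,
                    qtl_snp_index=qtl_snp_index,
                    qtl_dosage=dosage.astype(np.int8),
                    phenotypes=phenotypes)
    return F2Population(params=params, snps=snps, genotypes=genotypes,
                        phenotypes=phenotypes, truth=truth)


def select_extreme_bulks(phenotypes: np.ndarray,
                         pool_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the extreme-tail bulks: (high/dark, low/light).

    The low bulk holds the ``pool_size`` smallest phenotypes and the high
    bulk the ``pool_size`` largest.  Ties resolve by stable ascending
    sort, so among tied values the lowest indices go to the low bulk and
    the highest to the high bulk; the bulks are disjoint by construction.
    """
    phen = np.asarray(phenotypes, dtype=float)
    if phen.size < 2 * pool_size:
        raise ValueError("need at least 2 * pool_size phenotypes")
    order = np.argsort(phen, kind="stable")
    low = np.sort(order[:pool_size])
    high = np.sort(order[-pool_size:])
    return high, low


def simulate_pool_reads(population: F2Population, high_idx: np.ndarray,
                        low_idx: np.ndarray,
                        rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Pooled short-read allele counts for the two bulks at every SNP.

    Per SNP and bulk: depth ~ Poisson(depth_mean), floored at 1; the true
    mutant-allele frequency is the bulk's mean dosage / 2 (flipped when
    ``polarity`` is -1); each read reports the mutant allele with
    probability p*(1-e) + (1-p)*e.  Site base and mapping qualities are
    integers drawn in [30, 60], so the default filter keeps every site.

    Returns a canonical site table sorted by (chrom, pos).
    """
    params = population.params
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n_snps = len(population.snps)
    e = params.seq_error

    cols = {}
    for name, idx in (("high", high_idx), ("low", low_idx)):
        p = population.genotypes[idx].sum(axis=0) / (2.0 * len(idx))
        if params.polarity == -1:
            p = 1.0 - p
        p_obs = p * (1.0 - e) + (1.0 - p) * e
        depth = np.maximum(rng.poisson(params.depth_mean, size=n_snps), 1)
        alt = rng.binomial(depth, p_obs)
        cols[f"{name}_ref"] = depth - alt
        cols[f"{name}_alt"] = alt

    sites = pd.DataFrame({
        "chrom": population.snps["chrom"].to_numpy(),
        "pos": population.snps["pos"].to_numpy(),
        "ref": population.snps["ref"].to_numpy(),
        "alt": population.snps["alt"].to_numpy(),
        "high_ref": cols["high_ref"], "high_alt": cols["high_alt"],
        "low_ref": cols["low_ref"], "low_alt": cols["low_alt"],
        "bq": rng.integers(30, 61, size=n_snps).astype(float),
        "mq": rng.integers(30, 61, size=n_snps).astype(float),
    })[SITE_COLUMNS]
    return (sites.sort_values(["chrom", "pos"], kind="stable")
            .reset_index(drop=True))


@dataclass
class Experiment:
    """One complete simulated BSA-seq experiment."""

    population: F2Population
    sites: pd.DataFrame
    truth: F2Truth


def simulate_experiment(params: F2SimParams) -> Experiment:
    """Population -> extreme bulks -> pooled reads, all from one seed."""
    population = simulate_f2_population(params)
    high, low = select_extreme_bulks(population.phenotypes, params.pool_size)
    truth = replace_bulks(population.truth, high, low)
    population.truth = truth
    sites = simulate_pool_reads(population, high, low)
    return Experiment(population=population, sites=sites, truth=truth)


def replace_bulks(truth: F2Truth, high_idx: np.ndarray,
                  low_idx: np.ndarray) -> F2Truth:
    truth.high_idx = np.asarray(high_idx)
    truth.low_idx = np.asarray(low_idx)
    return truth


def write_fixture_vcf(sites: pd.DataFrame, path,
                      high_sample: str = "SL", low_sample: str = "QL",
                      chrom_lengths: dict | None = None) -> None:
    """Write simulated sites as the two-sample VCF dialect the parser reads."""
    write_pooled_vcf(sites, path, high_sample=high_sample,
                     low_sample=low_sample, chrom_lengths=chrom_lengths)


def write_truth_tsv(truth: F2Truth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# qtl_chrom={truth.qtl_chrom} qtl_pos={truth.qtl_pos}\n")
        fh.write("individual\tqtl_dosage\tphenotype\tbulk\n")
        high = set(truth.high_idx.tolist()) if truth.high_idx is not None \
            else set()
        low = set(truth.low_idx.tolist()) if truth.low_idx is not None \
            else set()
        for i, (dos, phe) in enumerate(
                zip(truth.qtl_dosage, truth.phenotypes)):
            bulk = "high" if i in high else ("low" if i in low else ".")
            fh.write(f"{i}\t{int(dos)}\t{phe!r}\t{bulk}\n")


def marker_grid(population: F2Population, max_markers: int = 500
                ) -> np.ndarray:
    """Evenly thinned SNP rows for the single-marker scan."""
    n = len(population.snps)
    if n <= max_markers:
        return np.arange(n)
    return np.unique(np.linspace(0, n - 1, max_markers).astype(int))


def write_phenogeno_tsv(population: F2Population, path,
                        max_markers: int = 500) -> np.ndarray:
    """Phenotype + thinned genotype table for the marker scan.

    Returns the SNP-row indices of the markers written.
    """
    grid = marker_grid(population, max_markers)
    snps = population.snps.iloc[grid]
    names = [f"{c}:{p}" for c, p in zip(snps["chrom"], snps["pos"])]
    df = pd.DataFrame(population.genotypes[:, grid], columns=names)
    df.insert(0, "phenotype", population.phenotypes)
    df.insert(0, "individual", np.arange(population.params.n_f2))
    df.to_csv(path, sep="\t", index=False)
    return grid
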