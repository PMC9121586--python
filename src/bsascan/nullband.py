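"""Monte-Carlo null distribution of delta(SNP-index) and confidence bands.

Under the null hypothesis of no QTL, an unlinked marker segregates freely
in the mapping population, so two bulks drawn at random (no phenotypic
selection) differ in allele frequency only through genotype sampling and
read sampling.  For each read depth the simulation:

1. draws ``pool_size`` genotypes per bulk from the cross's segregation
   (F2: alt-allele dosage ~ Binomial(2, 1/2), i.e. 0/1/2 with
   probabilities 1/4, 1/2, 1/4; RIL: 0/2 equally; BC1: 0/1 equally);
2. forms the pooled alt-allele frequency p = sum(dosage) / (2 * pool_size);
3. draws the bulk's alt read count ~ Binomial(depth, p) and divides by
   depth to get the bulk SNP-index;
4. takes delta = high-bulk index - low-bulk index,

iterated ``n_iterations`` times per depth.  Two-sided empirical quantiles
of the replicates give a depth-conditional confidence band; a windowed
delta(SNP-index) outside the band at its depth is declared significant.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POPULATIONS = ("F2", "RIL", "BC1")


@dataclass(frozen=True)
class NullSimConfig:
    """Configuration of the null simulation.

    Defaults mirror the bulked-segregant design this package emulates:
    F2 cross, bulks of 20, 10,000 replicates per depth, depths 1..100,
    two-sided 95% and 99% bands.
    """

    pool_size: int = 20
    population: str = "F2"
    n_iterations: int = 10_000
    depths: tuple = tuple(range(1, 101))
    ci_levels: tuple = (0.95, 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.population not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not self.depths or min(self.depths) < 1:
            raise ValueError("depths must be non-empty, all >= 1")
        if any(not 0.0 < lv < 1.0 for lv in self.ci_levels):
            raise ValueError("ci_levels must lie in (0, 1)")


def _draw_dosages(rng: np.random.Generator, population: str,
                  size) -> np.ndarray:
    """Alt-allele dosage of unlinked-marker genotypes for one cross type."""
    if population == "F2":
        return rng.binomial(2, 0.5, size=size)
    if population == "RIL":
        return 2 * rng.integers(0, 2, size=size)
    if population == "BC1":
        return rng.integers(0, 2, size=size)
    raise ValueError(f"unknown population {population!r}")


def _depth_rng(cfg: NullSimConfig, depth: int) -> np.random.Generator:
    # one independent, reproducible stream per (seed, depth); results do
    # not depend on the order depths are simulated in
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, depth]))


def simulate_null_delta(cfg: NullSimConfig, depth: int) -> np.ndarray:
    """Sample ``cfg.n_iterations`` null delta(SNP-index) values at a depth.

    Deterministic given ``cfg.seed`` (and independent of other depths).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _depth_rng(cfg, depth)
    deltas = np.empty(cfg.n_iterations)
    chunk = 100_000 if cfg.pool_size * cfg.n_iterations > 10_000_000 else \
        cfg.n_iterations
    done = 0
    while done < cfg.n_iterations:
        m = min(chunk, cfg.n_iterations - done)
        idx = np.empty((2, m))
        for b in range(2):
            dosage = _draw_dosages(rng, cfg.population, (m, cfg.pool_size))
            p = dosage.sum(axis=1) / (2 * cfg.pool_size)
            idx[b] = rng.binomial(depth, p) / depth
        deltas[done:done + m] = idx[0] - idx[1]
        done += m
    return deltas


@dataclass
class NullCITable:
    """Depth-indexed two-sided quantile bands of the null delta(SNP-index).

    ``bands`` maps (depth, level) -> (lower, upper); nearest-rank
    empirical quantiles at probabilities (1-level)/2 and 1-(1-level)/2.
    """

    config: NullSimConfig
    bands: dict = field(default_factory=dict)

    @property
    def depths(self) -> list[int]:
        return sorted({d for d, _ in self.bands})

    @property
    def levels(self) -> list[float]:
        return sorted({lv for _, lv in self.bands})

    def lookup(self, depth: float, level: float) -> tuple[float, float]:
        return lookup_ci(self, depth, level)

    def to_frame(self) -> pd.DataFrame:
        rows = [(d, lv, lo, up)
                for (d, lv), (lo, up) in sorted(self.bands.items())]
        return pd.DataFrame(rows, columns=["depth", "level", "lower", "upper"])

    def to_tsv(self, path) -> None:
        """Serialize losslessly (float values written as full repr)."""
        cfg = self.config
        with open(path, "w") as fh:
            fh.write(f"# null delta(SNP-index) CI table: "
                     f"population={cfg.population} pool_size={cfg.pool_size} "
                     f"n_iterations={cfg.n_iterations} seed={cfg.seed}\n")
            fh.write("depth\tlevel\tlower\tupper\n")
            for (d, lv), (lo, up) in sorted(self.bands.items()):
                fh.write(f"{d}\t{lv!r}\t{lo!r}\t{up!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "NullCITable":
        cfg = NullSimConfig()
        with open(path) as fh:
            header = fh.readline()
            if header.startswith("#"):
                kv = dict(tok.split("=", 1) for tok in
                          header.split(":", 1)[1].split() if "=" in tok)
                cfg = NullSimConfig(
                    pool_size=int(kv.get("pool_size", 20)),
                    population=kv.get("population", "F2"),
                    n_iterations=int(kv.get("n_iterations", 10_000)),
                    seed=int(kv.get("seed", 0)),
                )
                body = fh.read()
            else:
                body = header + fh.read()
        df = pd.read_csv(io.StringIO(body), sep="\t",
                         float_precision="round_trip")
        bands = {(int(r.depth), float(r.level)): (float(r.lower), float(r.upper))
                 for r in df.itertuples(index=False)}
        depths = tuple(sorted({d for d, _ in bands}))
        levels = tuple(sorted({lv for _, lv in bands}))
        cfg = NullSimConfig(pool_size=cfg.pool_size, population=cfg.population,
                            n_iterations=cfg.n_iterations, depths=depths,
                            ci_levels=levels, seed=cfg.seed)
        return cls(config=cfg, bands=bands)


def build_ci_table(cfg: NullSimConfig) -> NullCITable:
    """Simulate every depth in ``cfg.depths`` and tabulate quantile bands."""
    bands = {}
    for depth in cfg.depths:
        sample = simulate_null_delta(cfg, depth)
        for level in cfg.ci_levels:
            alpha = 1.0 - level
            lo, up = np.quantile(sample, [alpha / 2, 1 - alpha / 2],
                                 method="inverted_cdf")
            bands[(int(depth), float(level))] = (float(lo), float(up))
    return NullCITable(config=cfg, bands=bands)


def lookup_ci(table: NullCITable, depth: float,
              level: float) -> tuple[float, float]:
    """Band for the tabulated depth nearest the query.

    Ties break toward the smaller depth (the wider, more conservative
    band); queries beyond the grid clamp to the nearest end.
    """
    if not table.bands:
        raise ValueError("empty CI table")
    levels = table.levels
    if level not in levels:
        raise KeyError(f"level {level} not tabulated; available: {levels}")
    grid = table.depths
    best = min(grid, key=lambda d: (abs(d - depth), d))
    return table.bands[(best, level)]
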