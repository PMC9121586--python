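"""End-to-end scan orchestration: parse -> filter -> index -> window ->
null band -> candidate regions, with reproducible seeding and caching.

Every artifact is stamped with a hash of the run configuration and the
seed; rerunning with identical inputs and seed reproduces the TSV outputs
bit for bit.  The null CI table dominates runtime and is cached keyed by
its full configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import index as idx
from . import nullband, regions, variants
from .simulate import (F2SimParams, simulate_experiment, write_fixture_vcf,
                       write_phenogeno_tsv, write_truth_tsv)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one genome scan needs."""

    input_path: str
    high_sample: str = "SL"
    low_sample: str = "QL"
    chrom_lengths: dict = field(default_factory=dict)
    thresholds: variants.FilterThresholds = field(
        default_factory=variants.FilterThresholds)
    window: idx.WindowConfig = field(default_factory=idx.WindowConfig)
    nullsim: nullband.NullSimConfig = field(
        default_factory=nullband.NullSimConfig)
    level: float = 0.99
    min_windows: int = 1
    outdir: str = "results/scan"
    seed: int = 0
    ci_cache: str | None = None
    make_plot: bool = True

    def config_hash(self) -> str:
        def enc(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return asdict(obj)
            return str(obj)
        payload = asdict(self)
        # where outputs land does not change what is computed
        for key in ("outdir", "ci_cache", "make_plot"):
            payload.pop(key, None)
        blob = json.dumps(payload, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ScanResult:
    windows: pd.DataFrame
    regions: list
    ci_table: nullband.NullCITable
    filter_tally: dict
    outdir: Path


def _load_or_build_ci(cfg: RunConfig) -> nullband.NullCITable:
    nscfg = cfg.nullsim
    if cfg.ci_cache is not None:
        key = (f"ci_{nscfg.population}_p{nscfg.pool_size}"
               f"_i{nscfg.n_iterations}_d{min(nscfg.depths)}-"
               f"{max(nscfg.depths)}_s{nscfg.seed}.tsv")
        cache = Path(cfg.ci_cache) / key
        if cache.exists():
            logger.info("ci_table cache=hit path=%s", cache)
            return nullband.NullCITable.from_tsv(cache)
        table = nullband.build_ci_table(nscfg)
        cache.parent.mkdir(parents=True, exist_ok=True)
        table.to_tsv(cache)
        logger.info("ci_table cache=miss path=%s", cache)
        return table
    return nullband.build_ci_table(nscfg)


def run_scan(cfg: RunConfig, sites: pd.DataFrame | None = None,
             ci_table: nullband.NullCITable | None = None) -> ScanResult:
    """Execute the full scan and write its artifacts under ``cfg.outdir``.

    ``sites`` (a pre-parsed site table) and ``ci_table`` may be injected
    to skip parsing/simulation; otherwise the VCF or site table at
    ``cfg.input_path`` is read and the null table is built or loaded from
    cache.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n"

    if sites is None:
        path = str(cfg.input_path)
        if path.endswith((".vcf", ".vcf.gz")):
            sites = variants.parse_pooled_vcf(
                path, cfg.high_sample, cfg.low_sample)
        else:
            sites = variants.read_site_table(path)
    kept, tally = variants.filter_snps(sites, cfg.thresholds,
                                       return_tally=True)
    logger.info("scan filter excluded_bq=%d excluded_depth=%d excluded_mq=%d",
                tally["bq"], tally["depth"], tally["mq"])

    chrom_lengths = cfg.chrom_lengths or {
        c: int(g["pos"].max()) for c, g in kept.groupby("chrom")}

    if kept.empty:
        logger.warning("scan empty_filtered_set=1 — writing empty outputs")
        windows = idx.sliding_window(
            idx.compute_indices(kept), cfg.window, chrom_lengths)
        called = []
        table = ci_table if ci_table is not None else _load_or_build_ci(cfg)
    else:
        records = idx.compute_indices(kept)
        windows = idx.sliding_window(records, cfg.window, chrom_lengths)
        table = ci_table if ci_table is not None else _load_or_build_ci(cfg)
        called = regions.call_candidate_regions(
            windows, table, cfg.level, cfg.min_windows)

    with open(outdir / "windows.tsv", "w") as fh:
        fh.write(stamp)
        windows.to_csv(fh, sep="\t", index=False)
    with open(outdir / "regions.tsv", "w") as fh:
        fh.write(stamp)
        regions.regions_to_frame(called).to_csv(fh, sep="\t", index=False)
    regions.write_regions_bed(called, outdir / "regions.bed")
    table.to_tsv(outdir / "ci_table.tsv")
    if cfg.make_plot and not windows.empty:
        from .plotting import plot_delta_scan
        plot_delta_scan(windows, table, cfg.level, called,
                        outdir / "delta_scan.png")
    return ScanResult(windows=windows, regions=called, ci_table=table,
                      filter_tally=tally, outdir=outdir)


def run_simulate(params: F2SimParams, outdir) -> dict:
    """Simulate one experiment and write its fixture bundle.

    Writes the two-sample VCF, the ground-truth table, and a
    phenotype/genotype table for the marker scan; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = simulate_experiment(params)
    paths = {
        "vcf": outdir / "pools.vcf",
        "truth": outdir / "truth.tsv",
        "phenogeno": outdir / "phenogeno.tsv",
    }
    write_fixture_vcf(exp.sites, paths["vcf"],
                      chrom_lengths=params.chrom_lengths)
    write_truth_tsv(exp.truth, paths["truth"])
    write_phenogeno_tsv(exp.population, paths["phenogeno"])
    logger.info("simulate n_sites=%d n_f2=%d bulks=%d+%d seed=%d",
                len(exp.sites), params.n_f2, params.pool_size,
                params.pool_size, params.seed)
    return {k: str(v) for k, v in paths.items()}
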