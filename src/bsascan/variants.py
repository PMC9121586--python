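"""Pooled variant sites: parsing, validation and quality filtering.

A BSA-seq experiment sequences two pooled DNA bulks of phenotypically
extreme segregants against a reference genome.  The unit of analysis is a
biallelic SNP with per-bulk reference/alternate read counts.  Site
collections are pandas DataFrames with the canonical columns in
:data:`SITE_COLUMNS`; :class:`PooledVariant` is the single-site atom.

Coordinates are 1-based throughout, as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Canonical column order of a pooled site table.  ``high_*`` is the
#: high-phenotype (dark, "SL") bulk, ``low_*`` the low (light, "QL") bulk;
#: ``bq`` is the Phred site base quality, ``mq`` the RMS mapping quality.
SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "high_ref", "high_alt", "low_ref", "low_alt",
    "bq", "mq",
]

_NUCLEOTIDES = frozenset("ACGT")


class PooledVariantError(ValueError):
    """Malformed pooled-variant input (bad file, missing sample or field)."""


@dataclass(frozen=True)
class BulkCounts:
    """Read counts for one bulk at one site."""

    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic SNP with per-bulk counts and quality metadata."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    high_pool: BulkCounts
    low_pool: BulkCounts
    base_quality: float
    mapping_quality: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in _NUCLEOTIDES:
                raise ValueError(f"allele must be one of A,C,G,T: {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be non-negative")

    @classmethod
    def from_row(cls, row) -> "PooledVariant":
        """Build from one row of a canonical site table."""
        return cls(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref_allele=str(row["ref"]),
            alt_allele=str(row["alt"]),
            high_pool=BulkCounts(int(row["high_ref"]), int(row["high_alt"])),
            low_pool=BulkCounts(int(row["low_ref"]), int(row["low_alt"])),
            base_quality=float(row["bq"]),
            mapping_quality=float(row["mq"]),
        )

    def to_row(self) -> dict:
        return {
            "chrom": self.chrom, "pos": self.pos,
            "ref": self.ref_allele, "alt": self.alt_allele,
            "high_ref": self.high_pool.ref_count,
            "high_alt": self.high_pool.alt_count,
            "low_ref": self.low_pool.ref_count,
            "low_alt": self.low_pool.alt_count,
            "bq": self.base_quality, "mq": self.mapping_quality,
        }


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive-keep quality thresholds: sites *below* any are excluded."""

    min_base_quality: float = 30.0
    min_depth: int = 2
    min_mapping_quality: float = 30.0

    def __post_init__(self) -> None:
        if min(self.min_base_quality, self.min_depth, self.min_mapping_quality) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class ParseStats:
    """Bookkeeping from a VCF parse: retained and skipped line counts."""

    n_sites: int = 0
    n_skipped_indel: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_symbolic: int = 0

    @property
    def n_skipped(self) -> int:
        return (self.n_skipped_indel + self.n_skipped_multiallelic
                + self.n_skipped_symbolic)


def _empty_site_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        SITE_COLUMNS,
        [str, np.int64, str, str,
         np.int64, np.int64, np.int64, np.int64, float, float])})
    return df


def parse_pooled_vcf(path, high_sample: str, low_sample: str,
                     return_stats: bool = False):
    """Read a two-sample VCF into a canonical site table.

    Only biallelic SNP lines are kept; indel, multiallelic and symbolic
    lines are skipped and counted.  Per-bulk depths come from the
    per-sample ``AD`` allelic depths, never from ``DP``.  Base quality is
    the site ``QUAL``; mapping quality is ``INFO/MQ`` (0 if absent).

    Parameters
    ----------
    path : str or Path
        Uncompressed or bgzipped VCF.
    high_sample, low_sample : str
        Sample names of the high- (dark) and low- (light) phenotype bulks.
    return_stats : bool
        Also return a :class:`ParseStats`.

    Returns
    -------
    DataFrame sorted by (chrom, pos), columns :data:`SITE_COLUMNS`;
    optionally ``(df, ParseStats)``.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    for name in (high_sample, low_sample):
        if name not in samples:
            raise PooledVariantError(
                f"sample {name!r} not in VCF header (has {samples})")

    stats = ParseStats()
    rows = []
    for lineno, rec in enumerate(vcf, start=1):
        alts = rec.alts or ()
        if len(alts) != 1:
            stats.n_skipped_multiallelic += 1
            continue
        ref, alt = rec.ref, alts[0]
        if ref is None or alt is None or alt.startswith("<"):
            stats.n_skipped_symbolic += 1
            continue
        if len(ref) != 1 or len(alt) != 1 or \
                ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            stats.n_skipped_indel += 1
            continue
        counts = {}
        for name in (high_sample, low_sample):
            ad = rec.samples[name].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None:
                raise PooledVariantError(
                    f"record {lineno} ({rec.chrom}:{rec.pos}): sample "
                    f"{name!r} has no AD allelic-depth field")
            counts[name] = (int(ad[0]), int(ad[1]))
        mq = rec.info.get("MQ", 0.0)
        rows.append((
            rec.chrom, rec.pos, ref, alt,
            counts[high_sample][0], counts[high_sample][1],
            counts[low_sample][0], counts[low_sample][1],
            float(rec.qual if rec.qual is not None else 0.0), float(mq),
        ))
        stats.n_sites += 1
    vcf.close()

    df = (pd.DataFrame(rows, columns=SITE_COLUMNS) if rows
          else _empty_site_table())
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    logger.info("parse_pooled_vcf sites=%d skipped_indel=%d "
                "skipped_multiallelic=%d skipped_symbolic=%d",
                stats.n_sites, stats.n_skipped_indel,
                stats.n_skipped_multiallelic, stats.n_skipped_symbolic)
    if return_stats:
        return df, stats
    return df


def read_site_table(path) -> pd.DataFrame:
    """Read the tab-separated site-table dialect (header = SITE_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise PooledVariantError(f"site table missing columns: {missing}")
    return (df[SITE_COLUMNS]
            .sort_values(["chrom", "pos"], kind="stable")
            .reset_index(drop=True))


def write_site_table(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def write_pooled_vcf(sites: pd.DataFrame, path,
                     high_sample: str = "SL", low_sample: str = "QL",
                     chrom_lengths: dict | None = None) -> None:
    """Write a site table as a minimal two-sample VCF 4.2 with GT:AD.

    Round-trips exactly through :func:`parse_pooled_vcf` (integer AD
    counts, QUAL = bq, INFO/MQ = mq).
    """
    sites = sites.reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,'
                 'Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        chroms = (list(chrom_lengths.items()) if chrom_lengths else
                  [(c, None) for c in
                   pd.unique(sites["chrom"]).tolist()])
        for chrom, length in chroms:
            if length is None:
                fh.write(f"##contig=<ID={chrom}>\n")
            else:
                fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{high_sample}\t{low_sample}\n")
        for row in sites.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.bq:g}\t.\tMQ={row.mq:g}\tGT:AD\t"
                f"./.:{int(row.high_ref)},{int(row.high_alt)}\t"
                f"./.:{int(row.low_ref)},{int(row.low_alt)}\n")


def filter_snps(sites: pd.DataFrame,
                thresholds: FilterThresholds = FilterThresholds(),
                return_tally: bool = False):
    """Apply the low-quality SNP exclusion rules.

    A site is retained iff base quality >= ``min_base_quality`` AND mapping
    quality >= ``min_mapping_quality`` AND read depth >= ``min_depth`` in
    *both* bulks (per-bulk depth keeps the SNP-index defined downstream).
    Order is preserved.

    Returns the retained table; with ``return_tally=True`` also a dict
    ``{"bq": n, "depth": n, "mq": n}`` counting, per rule, how many sites
    violated it (a site failing several rules increments each).
    """
    depth_high = sites["high_ref"] + sites["high_alt"]
    depth_low = sites["low_ref"] + sites["low_alt"]
    fail_bq = sites["bq"] < thresholds.min_base_quality
    fail_mq = sites["mq"] < thresholds.min_mapping_quality
    fail_depth = (depth_high < thresholds.min_depth) | \
                 (depth_low < thresholds.min_depth)
    keep = ~(fail_bq | fail_mq | fail_depth)
    tally = {"bq": int(fail_bq.sum()), "depth": int(fail_depth.sum()),
             "mq": int(fail_mq.sum())}
    logger.info("filter_snps kept=%d excluded_bq=%d excluded_depth=%d "
                "excluded_mq=%d", int(keep.sum()),
                tally["bq"], tally["depth"], tally["mq"])
    out = sites.loc[keep].reset_index(drop=True)
    if return_tally:
        return out, tally
    return out


def filter_parent_informative(sites: pd.DataFrame,
                              parent_high_gt: pd.Series,
                              parent_low_gt: pd.Series) -> pd.DataFrame:
    """Optional parent-informed filter.

    Keeps only sites where the two parents are fixed for opposite alleles
    (dosage 2 in one parent, 0 in the other); heterozygous or missing
    parent calls drop the site.  ``parent_*_gt`` are alt-allele dosages
    aligned to ``sites`` rows (NaN = missing).
    """
    ph = pd.to_numeric(parent_high_gt, errors="coerce")
    pl = pd.to_numeric(parent_low_gt, errors="coerce")
    keep = ((ph == 2) & (pl == 0)) | ((ph == 0) & (pl == 2))
    keep = keep.fillna(False).to_numpy(dtype=bool)
    logger.info("filter_parent_informative kept=%d dropped=%d",
                int(keep.sum()), int((~keep).sum()))
    return sites.loc[keep].reset_index(drop=True)
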