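"""Reading, filtering and summarising pooled-sequencing variants.

A "pooled" VCF carries one sample per population; per-site allele read
depths live in the AD FORMAT field. All statistics downstream work on
these read counts directly — individual genotypes do not exist for a
pool.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a pooled VCF cannot be mapped onto the internal model."""


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic SNV with per-population (ref, alt) read counts.

    ``pos`` is 1-based, as in VCF. ``counts`` holds one ``(ref_reads,
    alt_reads)`` pair per population, in the population order used
    throughout a run.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    qual: float
    counts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref!r}/{self.alt!r}")
        for pair in self.counts:
            if pair[0] < 0 or pair[1] < 0:
                raise ValueError("read counts must be non-negative")

    @property
    def n_populations(self) -> int:
        return len(self.counts)

    def depth(self, population: int) -> int:
        r, a = self.counts[population]
        return r + a

    def total_depth(self) -> int:
        return sum(r + a for r, a in self.counts)

    def total_alt(self) -> int:
        return sum(a for _, a in self.counts)


@dataclass(frozen=True)
class FilterConfig:
    """SNV retention thresholds; all comparisons are inclusive (>=).

    ``min_total_coverage`` applies to the depth summed over all pools by
    default; set ``per_pool_coverage=True`` to require every single pool
    to reach the threshold instead.
    """

    min_qual: float = 30.0
    min_total_coverage: int = 68
    min_alt_reads: int = 3
    biallelic_only: bool = True
    per_pool_coverage: bool = False

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_total_coverage < 0 or self.min_alt_reads < 0:
            raise ValueError("filter thresholds must be >= 0")


def read_pooled_vcf(
    path: str, population_names: Sequence[str]
) -> tuple[list[PooledVariant], Counter]:
    """Read a pooled VCF into :class:`PooledVariant` records.

    Returns ``(variants, skip_counts)`` where ``skip_counts`` tallies
    lines dropped for being multi-allelic or not single-base SNVs.

    Raises :class:`VcfParseError` if a requested population is missing
    from the VCF samples or an AD field is malformed.
    """
    skip_counts: Counter = Counter()
    variants: list[PooledVariant] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        missing = [p for p in population_names if p not in samples]
        if missing:
            raise VcfParseError(f"populations absent from VCF samples: {missing}")
        for record_no, rec in enumerate(vf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                skip_counts["multiallelic"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                skip_counts["non_snv"] += 1
                continue
            counts = []
            for name in population_names:
                ad = rec.samples[name].get("AD")
                if ad is None or len(ad) != 2 or any(v is None for v in ad):
                    raise VcfParseError(
                        f"malformed AD for sample {name!r} at record {record_no} "
                        f"({rec.contig}:{rec.pos})"
                    )
                counts.append((int(ad[0]), int(ad[1])))
            qual = float(rec.qual) if rec.qual is not None else float("nan")
            variants.append(
                PooledVariant(rec.contig, rec.pos, ref, alt, qual, tuple(counts))
            )
    if skip_counts:
        logger.info("read_pooled_vcf skipped lines: %s", dict(skip_counts))
    return variants, skip_counts


def write_pooled_vcf(
    variants: Iterable[PooledVariant],
    path: str,
    population_names: Sequence[str],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write variants as an uncompressed VCF 4.2 with per-pool AD fields."""
    variants = list(variants)
    header = pysam.VariantHeader()
    if contig_lengths is None:
        contig_lengths = {}
        for v in variants:
            contig_lengths[v.contig] = max(contig_lengths.get(v.contig, 0), v.pos)
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.formats.add("AD", "R", "Integer", "Read depth for each allele")
    for name in population_names:
        header.add_sample(name)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                qual=v.qual,
            )
            for name, (r, a) in zip(population_names, v.counts):
                rec.samples[name]["AD"] = (r, a)
            out.write(rec)


def filter_variants(
    variants: Sequence[PooledVariant], config: FilterConfig | None = None
) -> tuple[list[PooledVariant], Counter]:
    """Apply the SNV retention rules.

    A variant is kept iff QUAL >= min_qual, coverage >= min_total_coverage
    (summed over pools, or per pool when configured) and the summed
    alternate-read count >= min_alt_reads. Rejections are attributed to
    the first failing rule, checked in the order biallelic, qual,
    coverage, alt-reads.
    """
    if config is None:
        config = FilterConfig()
    kept: list[PooledVariant] = []
    rejected: Counter = Counter()
    for v in variants:
        if config.biallelic_only and (
            len(v.ref) != 1 or len(v.alt) != 1 or v.ref not in _BASES or v.alt not in _BASES
        ):
            rejected["biallelic"] += 1
            continue
        if not v.qual >= config.min_qual:
            rejected["qual"] += 1
            continue
        if config.per_pool_coverage:
            coverage_ok = all(v.depth(i) >= config.min_total_coverage for i in range(v.n_populations))
        else:
            coverage_ok = v.total_depth() >= config.min_total_coverage
        if not coverage_ok:
            rejected["coverage"] += 1
            continue
        if v.total_alt() < config.min_alt_reads:
            rejected["alt_reads"] += 1
            continue
        kept.append(v)
    return kept, rejected


def stack_counts(
    variants: Sequence[PooledVariant],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Decompose variants into parallel arrays for vectorised statistics.

    Returns ``(contigs, pos, ref_counts, alt_counts, qual)`` where
    ``ref_counts``/``alt_counts`` have shape ``(n_variants, n_pops)``.
    """
    n = len(variants)
    if n == 0:
        return (
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
            np.empty((0, 0), dtype=np.int64),
            np.empty((0, 0), dtype=np.int64),
            np.empty(0, dtype=float),
        )
    contigs = np.array([v.contig for v in variants], dtype=object)
    pos = np.array([v.pos for v in variants], dtype=np.int64)
    counts = np.array([v.counts for v in variants], dtype=np.int64)
    refc = counts[:, :, 0]
    altc = counts[:, :, 1]
    qual = np.array([v.qual for v in variants], dtype=float)
    return contigs, pos, refc, altc, qual


def maf_spectrum(
    variants: Sequence[PooledVariant], population: int, n_bins: int = 10
) -> np.ndarray:
    """Minor-allele-frequency spectrum for one pool, in 10 equal bins.

    MAF per SNV is ``min(ref, alt) / (ref + alt)`` from that pool's read
    counts; bins are [0,0.05), ..., [0.45,0.5] and the returned
    proportions sum to 1. Zero-depth sites are excluded with a warning.
    """
    mafs = []
    n_zero = 0
    for v in variants:
        r, a = v.counts[population]
        tot = r + a
        if tot == 0:
            n_zero += 1
            continue
        mafs.append(min(r, a) / tot)
    if n_zero:
        warnings.warn(f"{n_zero} zero-depth sites excluded from MAF spectrum")
    if not mafs:
        raise ValueError("no sites with nonzero depth in this population")
    maf = np.asarray(mafs)
    idx = np.minimum((maf * 2 * n_bins).astype(int), n_bins - 1)
    hist = np.bincount(idx, minlength=n_bins).astype(float)
    return hist / hist.sum()


def zygosity_summary(
    variants: Sequence[PooledVariant], population: int
) -> tuple[int, int]:
    """Count (homozygote, heterozygote) SNVs for one pool.

    A pool is scored homozygous at an SNV when one of its two alleles has
    zero reads (the pool appears fixed), heterozygous otherwise. Sites
    with zero depth in the pool are not counted.
    """
    hom = het = 0
    for v in variants:
        r, a = v.counts[population]
        if r + a == 0:
            continue
        if r == 0 or a == 0:
            hom += 1
        else:
            het += 1
    return hom, het
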