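"""Pairwise Fst from pooled read counts, and the per-population di score.

Every read is treated as one sampled allele. Per SNV the estimator is a
one-way ANOVA on allele indicators across the two pools: MSP is the
among-population mean square, MSG the within-population mean square, and
the sample-size coefficient ``nc = (N - sum(a_i^2)/N) / (r - 1)`` for
pool depths ``a_i``. The per-SNV estimate is
``(MSP - MSG) / (MSP + (nc - 1) * MSG)``; windows combine SNVs by the
ratio-of-sums of these numerators and denominators, clamped to [0, 1].

``di`` for population i and a window sums, over every other population
j, the pairwise window Fst standardised by its genome-wide mean and sd.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .variant_io import PooledVariant, stack_counts
from .windows import GenomeWindow


class FstComponents(NamedTuple):
    msp: float
    msg: float
    n: float  # unequal-sample-size coefficient nc
    fst: float  # clamped to [0, 1]


@dataclass
class FstRecord:
    window: GenomeWindow
    pair: tuple[int, int]
    numerator: float
    denominator: float
    fst: float | None  # clamped; None when no usable SNV


@dataclass
class PairStats:
    pair: tuple[int, int]
    mean_fst: float
    sd_fst: float


@dataclass
class DiTrack:
    population: int
    records: list[tuple[GenomeWindow, float | None]]

    def values(self) -> np.ndarray:
        return np.array(
            [np.nan if d is None else d for _, d in self.records], dtype=float
        )


def per_snv_fst(
    counts_i: tuple[int, int], counts_j: tuple[int, int]
) -> FstComponents | None:
    """Mean-squares Fst components for a single SNV between two pools.

    ``counts_*`` are (ref_reads, alt_reads). Returns ``None`` when the
    SNV is unusable: zero depth in either pool, fewer than 3 total
    reads (the within mean square needs N - 2 > 0), or a site
    monomorphic in both pools (0/0 estimate).
    """
    r1, a1 = counts_i
    r2, a2 = counts_j
    c1, c2 = r1 + a1, r2 + a2
    if c1 == 0 or c2 == 0:
        return None
    N = c1 + c2
    if N <= 2:
        return None
    p1, p2 = a1 / c1, a2 / c2
    pbar = (a1 + a2) / N
    msp = c1 * (p1 - pbar) ** 2 + c2 * (p2 - pbar) ** 2  # r - 1 = 1
    msg = (c1 * p1 * (1.0 - p1) + c2 * p2 * (1.0 - p2)) / (N - 2)
    nc = N - (c1 * c1 + c2 * c2) / N  # (N - sum a^2 / N) / (r - 1)
    denominator = msp + (nc - 1.0) * msg
    if denominator == 0.0:
        return None
    raw = (msp - msg) / denominator
    return FstComponents(msp, msg, nc, min(1.0, max(0.0, raw)))


def window_fst(components: Sequence[FstComponents | None]) -> float | None:
    """Multi-locus window estimate: ratio of summed numerators/denominators."""
    num = 0.0
    den = 0.0
    usable = 0
    for comp in components:
        if comp is None:
            continue
        num += comp.msp - comp.msg
        den += comp.msp + (comp.n - 1.0) * comp.msg
        usable += 1
    if usable == 0 or den == 0.0:
        return None
    return min(1.0, max(0.0, num / den))


def _pair_site_terms(
    refc: np.ndarray, altc: np.ndarray, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNV (numerator, denominator) arrays for pools i, j; NaN = unusable."""
    c1 = (refc[:, i] + altc[:, i]).astype(float)
    c2 = (refc[:, j] + altc[:, j]).astype(float)
    N = c1 + c2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = altc[:, i] / c1
        p2 = altc[:, j] / c2
        pbar = (altc[:, i] + altc[:, j]) / N
        msp = c1 * (p1 - pbar) ** 2 + c2 * (p2 - pbar) ** 2
        msg = (c1 * p1 * (1.0 - p1) + c2 * p2 * (1.0 - p2)) / (N - 2.0)
        nc = N - (c1 * c1 + c2 * c2) / N
    num = msp - msg
    den = msp + (nc - 1.0) * msg
    bad = (c1 == 0) | (c2 == 0) | (N <= 2)
    bad |= ~np.isfinite(num) | ~np.isfinite(den) | (den == 0.0)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def pairwise_window_fst(
    variants: Sequence[PooledVariant],
    windows: Sequence[GenomeWindow],
    pair: tuple[int, int],
) -> list[FstRecord]:
    """Window Fst for one population pair over many windows (vectorised)."""
    i, j = pair
    _, _, refc, altc, _ = stack_counts(variants)
    if refc.size:
        num, den = _pair_site_terms(refc, altc, i, j)
    records = []
    for w in windows:
        idx = np.asarray(w.snv_indices, dtype=np.intp)
        if len(idx) == 0:
            records.append(FstRecord(w, pair, 0.0, 0.0, None))
            continue
        wn = num[idx]
        wd = den[idx]
        ok = ~np.isnan(wd)
        if not ok.any():
            records.append(FstRecord(w, pair, 0.0, 0.0, None))
            continue
        s_num = float(np.cumsum(wn[ok])[-1])
        s_den = float(np.cumsum(wd[ok])[-1])
        fst = None if s_den == 0.0 else min(1.0, max(0.0, s_num / s_den))
        records.append(FstRecord(w, pair, s_num, s_den, fst))
    return records


def compute_pair_stats(fst_records: Sequence[FstRecord]) -> PairStats:
    """Genome-wide mean/sd of window Fst for one pair, over defined windows."""
    pairs = {r.pair for r in fst_records}
    if len(pairs) != 1:
        raise ValueError("records must all belong to a single pair")
    vals = np.array([r.fst for r in fst_records if r.fst is not None], dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 defined windows for pair stats")
    if vals.max() == vals.min():
        raise ValueError("sd of window Fst is zero; degenerate input")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    return PairStats(pairs.pop(), mean, sd)


def compute_di(
    fst_by_pair: dict[tuple[int, int], Sequence[FstRecord]],
    pair_stats: dict[tuple[int, int], PairStats],
    population: int,
) -> DiTrack:
    """Standardised-sum divergence score for one population per window.

    ``di = sum_{j != i} (Fst_ij - mean_ij) / sd_ij`` over the windows
    shared by every pair involving the population; a window missing any
    pairwise Fst gets a missing di.
    """
    involved = sorted(p for p in fst_by_pair if population in p)
    if not involved:
        raise ValueError(f"no pairs involve population {population}")
    for p in involved:
        if p not in pair_stats:
            raise ValueError(f"missing pair stats for {p}")
    base = list(fst_by_pair[involved[0]])
    keys = [r.window.key for r in base]
    for p in involved[1:]:
        if [r.window.key for r in fst_by_pair[p]] != keys:
            raise ValueError("pairs computed over different window sets")
    records: list[tuple[GenomeWindow, float | None]] = []
    for k, rec in enumerate(base):
        di = 0.0
        ok = True
        for p in involved:
            f = fst_by_pair[p][k].fst
            if f is None:
                ok = False
                break
            st = pair_stats[p]
            di += (f - st.mean_fst) / st.sd_fst
        records.append((rec.window, di if ok else None))
    return DiTrack(population, records)


def di_threshold(di_values: Sequence[float], top_fraction: float = 0.01) -> float:
    """Empirical (1 - top_fraction) quantile of di; windows strictly above pass."""
    vals = np.asarray(
        [d for d in di_values if d is not None and not math.isnan(d)], dtype=float
    )
    if len(vals) == 0:
        raise ValueError("no defined di values")
    if len(vals) < 100:
        warnings.warn(
            f"only {len(vals)} windows available for the top-{top_fraction:.0%} cutoff"
        )
    return float(np.quantile(vals, 1.0 - top_fraction))
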