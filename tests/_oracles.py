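"""Independent brute-force oracles, written against the definitions only.

These deliberately avoid the package's vectorised code paths: plain
loops over individual allele indicators, ``statistics`` for moments.
They exist so every estimator has a second, independent route.
"""

from __future__ import annotations

import statistics


def hp_oracle(sum_major: int, sum_minor: int) -> float:
    total = sum_major + sum_minor
    return 2 * sum_major * sum_minor / total**2


def window_hp_oracle(counts: list[tuple[int, int]]) -> float:
    """counts: per-SNV (ref_reads, alt_reads) for one pool."""
    sum_major = sum(max(r, a) for r, a in counts)
    sum_minor = sum(min(r, a) for r, a in counts)
    return hp_oracle(sum_major, sum_minor)


def zscore_oracle(values: list[float]) -> list[float]:
    mu = statistics.fmean(values)
    sigma = statistics.pstdev(values)
    return [(v - mu) / sigma for v in values]


def fst_anova_oracle(
    counts_i: tuple[int, int], counts_j: tuple[int, int]
) -> tuple[float, float, float, float] | None:
    """One-way ANOVA on explicit 0/1 allele indicators for two pools.

    Returns (msp, msg, nc, fst_clamped) or None when undefined.
    """
    groups = []
    for r, a in (counts_i, counts_j):
        groups.append([1] * a + [0] * r)
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        return None
    N = sum(sizes)
    if N <= 2:
        return None
    r_groups = len(groups)
    grand = sum(sum(g) for g in groups) / N
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        mean_g = sum(g) / len(g)
        ss_between += len(g) * (mean_g - grand) ** 2
        for x in g:
            ss_within += (x - mean_g) ** 2
    msp = ss_between / (r_groups - 1)
    msg = ss_within / (N - r_groups)
    nc = (N - sum(s * s for s in sizes) / N) / (r_groups - 1)
    den = msp + (nc - 1) * msg
    if den == 0.0:
        return None
    raw = (msp - msg) / den
    return msp, msg, nc, min(1.0, max(0.0, raw))


def window_fst_oracle(
    snv_counts: list[tuple[tuple[int, int], tuple[int, int]]]
) -> float | None:
    """Ratio-of-sums over per-SNV ANOVA components; clamped to [0, 1]."""
    num = den = 0.0
    usable = 0
    for counts_i, counts_j in snv_counts:
        comp = fst_anova_oracle(counts_i, counts_j)
        if comp is None:
            continue
        msp, msg, nc, _ = comp
        num += msp - msg
        den += msp + (nc - 1) * msg
        usable += 1
    if usable == 0 or den == 0.0:
        return None
    return min(1.0, max(0.0, num / den))


def di_oracle(
    window_fst: dict[tuple[int, int], float],
    pair_mean: dict[tuple[int, int], float],
    pair_sd: dict[tuple[int, int], float],
    population: int,
) -> float:
    total = 0.0
    for pair, fst in window_fst.items():
        if population in pair:
            total += (fst - pair_mean[pair]) / pair_sd[pair]
    return total
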