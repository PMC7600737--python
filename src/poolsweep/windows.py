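"""Sliding-window pooled heterozygosity (Hp) and its Z-transform (ZHp).

Hp for a window is ``2 * sum_maj * sum_min / (sum_maj + sum_min)**2``
where ``sum_maj`` / ``sum_min`` accumulate, over the window's SNVs, the
read counts of each pool's major and minor allele. Windows with too few
SNVs are treated as missing — they enter neither the mean/sd used for
the Z-transform nor any downstream calling.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .variant_io import PooledVariant, stack_counts


@dataclass
class GenomeWindow:
    """Half-open, 0-based genomic interval with attached SNV membership."""

    contig: str
    start: int
    end: int
    snv_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty window [{self.start},{self.end})")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


@dataclass
class HpRecord:
    window: GenomeWindow
    population: int
    sum_major: int
    sum_minor: int
    n_snvs: int
    hp: float | None

    def __post_init__(self) -> None:
        if self.hp is not None and not (0.0 <= self.hp <= 0.5):
            raise ValueError(f"hp out of [0, 0.5]: {self.hp}")


@dataclass
class ZHpTrack:
    population: int
    mu_hp: float
    sigma_hp: float
    records: list[tuple[GenomeWindow, float]]

    def values(self) -> np.ndarray:
        return np.array([z for _, z in self.records], dtype=float)


def make_windows(
    contig_lengths: Mapping[str, int], size_bp: int, step_bp: int
) -> list[GenomeWindow]:
    """Tile every contig with sliding windows of ``size_bp`` every ``step_bp``.

    Window starts are 0, step, 2*step, ... while the start lies inside the
    contig; window ends are truncated at the contig end, so trailing
    windows may be shorter than ``size_bp``. Requires step <= size so
    that every bp is covered.
    """
    if size_bp <= 0 or step_bp <= 0:
        raise ValueError("window size and step must be positive")
    if step_bp > size_bp:
        raise ValueError("step larger than window size would leave gaps")
    windows: list[GenomeWindow] = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length")
        for start in range(0, length, step_bp):
            windows.append(GenomeWindow(contig, start, min(start + size_bp, length)))
    return windows


def expected_window_count(length: int, step_bp: int) -> int:
    """Closed-form number of windows :func:`make_windows` emits per contig."""
    return -(-length // step_bp)


def assign_snvs(windows: Sequence[GenomeWindow], variants: Sequence[PooledVariant]) -> None:
    """Populate ``window.snv_indices`` with indices into ``variants``.

    A variant at 1-based ``pos`` belongs to a window iff
    ``start <= pos - 1 < end``. With overlapping windows one SNV can be a
    member of several windows.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for i, v in enumerate(variants):
        by_contig.setdefault(v.contig, []).append((v.pos - 1, i))
    for contig in by_contig:
        by_contig[contig].sort()
    for w in windows:
        entries = by_contig.get(w.contig, [])
        pos0 = [p for p, _ in entries]
        lo = bisect_left(pos0, w.start)
        hi = bisect_left(pos0, w.end)
        w.snv_indices = [entries[k][1] for k in range(lo, hi)]


def _hp_value(sum_major: int, sum_minor: int) -> float | None:
    total = sum_major + sum_minor
    if total == 0:
        return None
    return 2.0 * sum_major * sum_minor / (total * total)


def pooled_heterozygosity(
    variants: Sequence[PooledVariant], window: GenomeWindow, population: int
) -> HpRecord:
    """Hp for one window and one pool, from read counts.

    Per SNV the major allele is the one with more reads in this pool
    (ties go to the reference allele); its read count accrues to
    ``sum_major`` and the other to ``sum_minor``. Hp is undefined
    (``None``) when the window holds no SNVs or no reads.
    """
    sum_major = sum_minor = 0
    for i in window.snv_indices:
        r, a = variants[i].counts[population]
        if a > r:
            sum_major += a
            sum_minor += r
        else:
            sum_major += r
            sum_minor += a
    n = len(window.snv_indices)
    hp = _hp_value(sum_major, sum_minor) if n > 0 else None
    return HpRecord(window, population, sum_major, sum_minor, n, hp)


def compute_hp_records(
    variants: Sequence[PooledVariant],
    windows: Sequence[GenomeWindow],
    population: int,
) -> list[HpRecord]:
    """Vectorised Hp over many windows; equals per-window recomputation."""
    _, _, refc, altc, _ = stack_counts(variants)
    if refc.size:
        maj = np.maximum(refc[:, population], altc[:, population])
        mnr = np.minimum(refc[:, population], altc[:, population])
    records = []
    for w in windows:
        idx = np.asarray(w.snv_indices, dtype=np.intp)
        n = len(idx)
        if n == 0:
            records.append(HpRecord(w, population, 0, 0, 0, None))
            continue
        sm = int(maj[idx].sum())
        sn = int(mnr[idx].sum())
        records.append(HpRecord(w, population, sm, sn, n, _hp_value(sm, sn)))
    return records


def retain_windows(
    hp_records: Sequence[HpRecord], min_snvs: int = 10
) -> list[HpRecord]:
    """Keep windows with strictly more than ``min_snvs`` SNVs and defined Hp."""
    kept = [r for r in hp_records if r.n_snvs > min_snvs and r.hp is not None]
    if not kept:
        warnings.warn("no windows retained; all below the SNV-count threshold")
    return kept


def z_transform(
    retained: Sequence[HpRecord], population: int | None = None, ddof: int = 0
) -> ZHpTrack:
    """Z-transform Hp across the retained windows of one population.

    The default ``ddof=0`` (population standard deviation) makes the
    resulting Z-scores have sd exactly 1.
    """
    recs = [r for r in retained if population is None or r.population == population]
    if population is None:
        pops = {r.population for r in recs}
        if len(pops) > 1:
            raise ValueError("records from several populations; pass population=")
        population = pops.pop() if pops else -1
    if len(recs) < 2:
        raise ValueError("need at least 2 retained windows to Z-transform")
    hps = np.array([r.hp for r in recs], dtype=float)
    mu = float(hps.mean())
    sigma = float(hps.std(ddof=ddof))
    if sigma == 0.0:
        raise ValueError("sigma(Hp) is zero; degenerate input")
    return ZHpTrack(
        population=population,
        mu_hp=mu,
        sigma_hp=sigma,
        records=[(r.window, float((r.hp - mu) / sigma)) for r in recs],
    )
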