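"""Calling selected loci from joint ZHp / di extremes and annotating genes.

A window is flagged when its ZHp falls strictly below the low cutoff
(default -7) AND its di rises strictly above the high cutoff (by default
the genome-wide top-1% quantile). Overlapping or bookended flagged
windows merge into loci; genes overlapping a locus by at least 1 bp are
reported with the locus extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import gffutils

from .differentiation import DiTrack
from .windows import GenomeWindow, ZHpTrack


@dataclass
class GeneModel:
    """Gene span parsed from GFF3, converted to 0-based half-open."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("gene end before start")


@dataclass
class FlaggedWindow:
    window: GenomeWindow
    population: int
    zhp: float
    di: float


@dataclass
class SelectionLocus:
    population: int
    contig: str
    start: int
    end: int
    min_zhp: float
    max_di: float
    n_windows: int
    genes: list[str] = field(default_factory=list)


@dataclass
class GeneReportRow:
    gene_id: str
    contig: str
    annotation: str
    zhp: float
    di: float
    population: int
    locus_start: int
    locus_end: int


def read_gene_models(gff_path: str) -> list[GeneModel]:
    """Parse gene features (with any CDS children) from a GFF3 file."""
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        name = g.attributes.get("Name", [None])[0]
        cds = [
            (c.start - 1, c.end)
            for c in db.children(g, featuretype="CDS", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand or ".",
                name=name,
                cds=cds,
            )
        )
    return genes


def flag_selected_windows(
    zhp_track: ZHpTrack,
    di_track: DiTrack,
    di_cutoff: float,
    zhp_cutoff: float = -7.0,
) -> list[FlaggedWindow]:
    """Windows jointly extreme: ``zhp < zhp_cutoff`` and ``di > di_cutoff``."""
    if [w.key for w, _ in zhp_track.records] != [w.key for w, _ in di_track.records]:
        raise ValueError("ZHp and di tracks cover different window sets")
    flagged = []
    for (w, z), (_, d) in zip(zhp_track.records, di_track.records):
        if d is None:
            continue
        if z < zhp_cutoff and d > di_cutoff:
            flagged.append(FlaggedWindow(w, zhp_track.population, z, d))
    return flagged


def merge_windows_to_loci(flagged: Sequence[FlaggedWindow]) -> list[SelectionLocus]:
    """Merge overlapping or bookended flagged windows into loci per contig."""
    if not flagged:
        return []
    pops = {f.population for f in flagged}
    if len(pops) != 1:
        raise ValueError("flagged windows from several populations")
    population = pops.pop()
    ordered = sorted(flagged, key=lambda f: (f.window.contig, f.window.start, f.window.end))
    loci: list[SelectionLocus] = []
    for f in ordered:
        w = f.window
        if loci and loci[-1].contig == w.contig and w.start <= loci[-1].end:
            cur = loci[-1]
            cur.end = max(cur.end, w.end)
            cur.min_zhp = min(cur.min_zhp, f.zhp)
            cur.max_di = max(cur.max_di, f.di)
            cur.n_windows += 1
        else:
            loci.append(
                SelectionLocus(
                    population=population,
                    contig=w.contig,
                    start=w.start,
                    end=w.end,
                    min_zhp=f.zhp,
                    max_di=f.di,
                    n_windows=1,
                )
            )
    return loci


def annotate_loci(
    loci: Sequence[SelectionLocus],
    genes: Sequence[GeneModel],
    known_contigs: set[str] | None = None,
) -> list[GeneReportRow]:
    """Report genes overlapping loci by >= 1 bp, carrying locus extremes.

    When ``known_contigs`` is given (e.g. VCF header contigs), gene
    records on unknown contigs raise an error naming the offenders.
    """
    if known_contigs is not None:
        offenders = sorted({g.contig for g in genes} - set(known_contigs))
        if offenders:
            raise ValueError(
                f"gene annotation contigs absent from variant data: {offenders}"
            )
    rows = []
    for locus in loci:
        for g in genes:
            if g.contig != locus.contig:
                continue
            if g.start < locus.end and locus.start < g.end:
                locus.genes.append(g.gene_id)
                rows.append(
                    GeneReportRow(
                        gene_id=g.gene_id,
                        contig=g.contig,
                        annotation=g.name or "",
                        zhp=locus.min_zhp,
                        di=locus.max_di,
                        population=locus.population,
                        locus_start=locus.start,
                        locus_end=locus.end,
                    )
                )
    return rows
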