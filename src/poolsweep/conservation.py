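"""Breed-specific SNVs intersected with multi-species conserved sites.

The screen takes pre-computed multi-FASTA alignments, one per gene. The
row whose id starts with ``reference|`` maps alignment columns back to
genomic coordinates; its description must carry a ``loc=<contig>:<start>``
tag giving the 0-based genomic position of its first aligned base.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence

from Bio import SeqIO

from .sweeps import GeneModel
from .variant_io import PooledVariant

GAP = "-"
_LOC_RE = re.compile(r"loc=(\S+):(\d+)")


@dataclass
class SpeciesAlignment:
    gene_id: str
    species: list[str]
    rows: list[str]
    reference_index: int
    ref_contig: str
    ref_start: int  # 0-based genomic position of the first reference base

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, c: int) -> list[str]:
        return [row[c] for row in self.rows]

    def coord_map(self) -> list[int | None]:
        """Genomic position (0-based) per column; None where the reference gaps."""
        out: list[int | None] = []
        pos = self.ref_start
        for ch in self.rows[self.reference_index]:
            if ch == GAP:
                out.append(None)
            else:
                out.append(pos)
                pos += 1
        return out


@dataclass
class ConservedSite:
    gene_id: str
    column: int
    genomic_pos: int | None  # 0-based; None when the reference row gaps
    base: str


@dataclass
class ConservedSnvRow:
    gene_id: str
    contig: str
    pos: int  # 1-based, as in the VCF
    population: int
    ref: str
    alt: str
    coding: bool


def read_alignment_fasta(path: str, gene_id: str | None = None) -> SpeciesAlignment:
    """Load one per-gene multi-FASTA alignment.

    The reference row is named ``reference|<gene_id>`` and its
    description carries ``loc=<contig>:<start>``.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) < 3:
        raise ValueError(f"{path}: need at least 3 aligned rows")
    ref_idx = None
    for i, rec in enumerate(records):
        if rec.id.startswith("reference|"):
            ref_idx = i
            break
    if ref_idx is None:
        raise ValueError(f"{path}: no row named reference|<gene_id>")
    ref = records[ref_idx]
    inferred_gene = ref.id.split("|", 1)[1]
    m = _LOC_RE.search(ref.description)
    if not m:
        raise ValueError(f"{path}: reference row lacks a loc=<contig>:<start> tag")
    return SpeciesAlignment(
        gene_id=gene_id or inferred_gene,
        species=[rec.id for rec in records],
        rows=[str(rec.seq) for rec in records],
        reference_index=ref_idx,
        ref_contig=m.group(1),
        ref_start=int(m.group(2)),
    )


def find_conserved_sites(
    alignment: SpeciesAlignment, max_gap_rows: int = 0
) -> list[ConservedSite]:
    """Columns where every non-gap row agrees (case-insensitively).

    A column qualifies when at most ``max_gap_rows`` rows are gaps and
    all remaining rows carry the same base. Conserved columns where the
    reference row itself gaps are reported without a genomic position.
    """
    sites = []
    coord = alignment.coord_map()
    for c in range(alignment.n_columns):
        col = [ch.upper() for ch in alignment.column(c)]
        gaps = col.count(GAP)
        if gaps > max_gap_rows:
            continue
        bases = {ch for ch in col if ch != GAP}
        if len(bases) != 1:
            continue
        sites.append(ConservedSite(alignment.gene_id, c, coord[c], bases.pop()))
    return sites


def breed_specific_snvs(
    variants: Sequence[PooledVariant],
    focal_population: int,
    presence_min: float = 0.9,
    absence_max: float = 0.1,
    regions: Sequence[tuple[str, int, int]] | None = None,
) -> list[PooledVariant]:
    """SNVs (nearly) fixed in the focal pool and (nearly) absent elsewhere.

    An SNV qualifies when one of its alleles has read frequency
    >= ``presence_min`` in the focal pool and <= ``absence_max`` in every
    other pool. ``regions`` optionally restricts the scan to 0-based
    half-open intervals (e.g. gene bodies plus flanks). Sites with a
    zero-depth pool are skipped with a warning.
    """
    if not 0.0 <= absence_max <= presence_min <= 1.0:
        raise ValueError("need 0 <= absence_max <= presence_min <= 1")
    out = []
    n_zero = 0
    for v in variants:
        if regions is not None and not any(
            v.contig == c and s <= v.pos - 1 < e for c, s, e in regions
        ):
            continue
        depths = [r + a for r, a in v.counts]
        if any(d == 0 for d in depths):
            n_zero += 1
            continue
        alt_freq = [a / d for (_, a), d in zip(v.counts, depths)]
        others = [f for i, f in enumerate(alt_freq) if i != focal_population]
        focal = alt_freq[focal_population]
        alt_specific = focal >= presence_min and all(f <= absence_max for f in others)
        ref_specific = (1.0 - focal) >= presence_min and all(
            (1.0 - f) <= absence_max for f in others
        )
        if alt_specific or ref_specific:
            out.append(v)
    if n_zero:
        warnings.warn(f"{n_zero} sites with a zero-depth pool skipped")
    return out


def gene_flank_regions(
    genes: Sequence[GeneModel],
    flank: int = 1000,
    contig_lengths: dict[str, int] | None = None,
) -> list[tuple[str, int, int]]:
    """Gene spans widened by ``flank`` bp each side, clipped to contig bounds."""
    regions = []
    for g in genes:
        start = max(0, g.start - flank)
        end = g.end + flank
        if contig_lengths is not None and g.contig in contig_lengths:
            end = min(end, contig_lengths[g.contig])
        regions.append((g.contig, start, end))
    return regions


def intersect_and_classify(
    specific_snvs: Sequence[PooledVariant],
    conserved_sites: Sequence[ConservedSite],
    genes: Sequence[GeneModel],
    focal_population: int,
    alignment_contigs: dict[str, str] | None = None,
) -> list[ConservedSnvRow]:
    """Breed-specific SNVs landing on conserved positions, labelled coding.

    ``alignment_contigs`` maps gene_id -> contig for the conserved sites
    (needed because :class:`ConservedSite` carries only gene and
    position); when omitted, gene contigs from ``genes`` are used.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    conserved_pos: dict[tuple[str, int], str] = {}
    for s in conserved_sites:
        if s.genomic_pos is None:
            continue
        if alignment_contigs is not None:
            contig = alignment_contigs[s.gene_id]
        else:
            gene = gene_by_id.get(s.gene_id)
            if gene is None:
                continue
            contig = gene.contig
        conserved_pos[(contig, s.genomic_pos)] = s.gene_id
    rows = []
    for v in specific_snvs:
        key = (v.contig, v.pos - 1)
        if key not in conserved_pos:
            continue
        gene_id = conserved_pos[key]
        gene = gene_by_id.get(gene_id)
        coding = False
        if gene is not None:
            coding = any(s <= v.pos - 1 < e for s, e in gene.cds)
        rows.append(
            ConservedSnvRow(
                gene_id=gene_id,
                contig=v.contig,
                pos=v.pos,
                population=focal_population,
                ref=v.ref,
                alt=v.alt,
                coding=coding,
            )
        )
    return rows
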