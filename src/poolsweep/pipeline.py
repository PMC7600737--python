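"""End-to-end orchestration: filter -> ZHp -> Fst/di -> calling -> conservation.

All stage parameters live in :class:`RunConfig`; defaults mirror the
published analysis settings (50 kb windows, >10 SNVs per window,
ZHp < -7, di in the top 1%, QUAL >= 30, summed coverage >= 68,
1000 bp gene flanks).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .conservation import (
    breed_specific_snvs,
    find_conserved_sites,
    gene_flank_regions,
    intersect_and_classify,
    read_alignment_fasta,
)
from .differentiation import (
    compute_di,
    compute_pair_stats,
    di_threshold,
    pairwise_window_fst,
)
from .sweeps import (
    annotate_loci,
    flag_selected_windows,
    merge_windows_to_loci,
    read_gene_models,
)
from .variant_io import FilterConfig, filter_variants, read_pooled_vcf
from .windows import (
    assign_snvs,
    compute_hp_records,
    make_windows,
    z_transform,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str = ""
    gff: str = ""
    alignments_dir: str = ""
    out_dir: str = "poolsweep_out"
    populations: list[str] = field(default_factory=list)
    window_size: int = 50_000
    window_step: int = 25_000
    min_snvs: int = 10
    min_qual: float = 30.0
    min_total_coverage: int = 68
    min_alt_reads: int = 3
    per_pool_coverage: bool = False
    zhp_cutoff: float = -7.0
    di_top_fraction: float = 0.01
    di_cutoff: float | None = None  # absolute override of the quantile rule
    presence_min: float = 0.9
    absence_max: float = 0.1
    flank: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    if not config.vcf:
        problems.append("vcf: no input VCF path configured")
    elif not Path(config.vcf).exists():
        problems.append(f"vcf: file not found: {config.vcf}")
    if config.gff and not Path(config.gff).exists():
        problems.append(f"gff: file not found: {config.gff}")
    if config.alignments_dir and not Path(config.alignments_dir).is_dir():
        problems.append(f"alignments_dir: not a directory: {config.alignments_dir}")
    if config.window_size <= 0:
        problems.append("window_size: must be positive")
    if config.window_step <= 0:
        problems.append("window_step: must be positive")
    elif config.window_step > config.window_size:
        problems.append("window_step: larger than window_size (would leave gaps)")
    if config.min_snvs < 0:
        problems.append("min_snvs: must be >= 0")
    if not 0.0 < config.di_top_fraction < 1.0:
        problems.append("di_top_fraction: must lie in (0, 1)")
    if not 0.0 <= config.absence_max <= config.presence_min <= 1.0:
        problems.append("presence_min/absence_max: need 0 <= absence <= presence <= 1")
    if config.flank < 0:
        problems.append("flank: must be >= 0")
    return problems


def _contig_lengths_from_vcf(path: str) -> dict[str, int]:
    import pysam

    with pysam.VariantFile(path) as vf:
        return {name: c.length for name, c in vf.header.contigs.items() if c.length}


def run_full_scan(config: RunConfig) -> dict:
    """Run every stage and write TSV/BED outputs plus a JSON manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    variants, skip_counts = read_pooled_vcf(config.vcf, config.populations)
    counts["vcf_records"] = len(variants)
    counts["vcf_skipped"] = int(sum(skip_counts.values()))

    fc = FilterConfig(
        min_qual=config.min_qual,
        min_total_coverage=config.min_total_coverage,
        min_alt_reads=config.min_alt_reads,
        per_pool_coverage=config.per_pool_coverage,
    )
    kept, rejected = filter_variants(variants, fc)
    counts["variants_kept"] = len(kept)
    counts["variants_rejected"] = int(sum(rejected.values()))
    logger.info("filter: kept %d, rejected %s", len(kept), dict(rejected))

    contig_lengths = _contig_lengths_from_vcf(config.vcf)
    if not contig_lengths:
        contig_lengths = {}
        for v in kept:
            contig_lengths[v.contig] = max(contig_lengths.get(v.contig, 0), v.pos)
    windows = make_windows(contig_lengths, config.window_size, config.window_step)
    assign_snvs(windows, kept)
    counts["windows_total"] = len(windows)

    n_pops = len(config.populations)
    # a single retained-window set shared by every population and pair:
    # enough SNVs and a defined Hp in all pools
    hp_by_pop = {p: compute_hp_records(kept, windows, p) for p in range(n_pops)}
    retained_idx = [
        k
        for k, w in enumerate(windows)
        if len(w.snv_indices) > config.min_snvs
        and all(hp_by_pop[p][k].hp is not None for p in range(n_pops))
    ]
    retained_windows = [windows[k] for k in retained_idx]
    zhp_rows = []
    zhp_tracks = {}
    for p in range(n_pops):
        retained = [hp_by_pop[p][k] for k in retained_idx]
        track = z_transform(retained, p)
        zhp_tracks[p] = track
        for rec, (w, z) in zip(retained, track.records):
            zhp_rows.append(
                {
                    "population": config.populations[p],
                    "contig": w.contig,
                    "start": w.start,
                    "end": w.end,
                    "n_snvs": rec.n_snvs,
                    "hp": rec.hp,
                    "zhp": z,
                }
            )
    counts["windows_retained"] = len(retained_windows or [])
    zhp_path = out_dir / "windows_zhp.tsv"
    pd.DataFrame(zhp_rows).to_csv(zhp_path, sep="\t", index=False)
    outputs["zhp"] = str(zhp_path)

    pairs = list(combinations(range(n_pops), 2))
    fst_by_pair = {
        pair: pairwise_window_fst(kept, retained_windows, pair) for pair in pairs
    }
    pair_stats = {pair: compute_pair_stats(fst_by_pair[pair]) for pair in pairs}
    fst_rows = []
    for pair in pairs:
        for r in fst_by_pair[pair]:
            fst_rows.append(
                {
                    "pop_i": config.populations[pair[0]],
                    "pop_j": config.populations[pair[1]],
                    "contig": r.window.contig,
                    "start": r.window.start,
                    "end": r.window.end,
                    "fst": r.fst,
                }
            )
    fst_path = out_dir / "windows_fst.tsv"
    pd.DataFrame(fst_rows).to_csv(fst_path, sep="\t", index=False)
    outputs["fst"] = str(fst_path)
    stats_path = out_dir / "pair_stats.tsv"
    pd.DataFrame(
        [
            {
                "pop_i": config.populations[p.pair[0]],
                "pop_j": config.populations[p.pair[1]],
                "mean_fst": p.mean_fst,
                "sd_fst": p.sd_fst,
            }
            for p in pair_stats.values()
        ]
    ).to_csv(stats_path, sep="\t", index=False)
    outputs["pair_stats"] = str(stats_path)

    di_rows = []
    di_tracks = {}
    for p in range(n_pops):
        track = compute_di(fst_by_pair, pair_stats, p)
        di_tracks[p] = track
        for w, d in track.records:
            di_rows.append(
                {
                    "population": config.populations[p],
                    "contig": w.contig,
                    "start": w.start,
                    "end": w.end,
                    "di": d,
                }
            )
    di_path = out_dir / "windows_di.tsv"
    pd.DataFrame(di_rows).to_csv(di_path, sep="\t", index=False)
    outputs["di"] = str(di_path)

    genes = read_gene_models(config.gff) if config.gff else []
    loci_rows = []
    report_rows = []
    all_loci = {}
    for p in range(n_pops):
        di_vals = di_tracks[p].values()
        cutoff = (
            config.di_cutoff
            if config.di_cutoff is not None
            else di_threshold(di_vals, config.di_top_fraction)
        )
        flagged = flag_selected_windows(
            zhp_tracks[p], di_tracks[p], di_cutoff=cutoff, zhp_cutoff=config.zhp_cutoff
        )
        loci = merge_windows_to_loci(flagged)
        all_loci[p] = loci
        for locus in loci:
            loci_rows.append(
                {
                    "contig": locus.contig,
                    "start": locus.start,
                    "end": locus.end,
                    "population": config.populations[p],
                    "min_zhp": locus.min_zhp,
                    "max_di": locus.max_di,
                    "n_windows": locus.n_windows,
                }
            )
        if genes:
            rows = annotate_loci(loci, genes, known_contigs=set(contig_lengths))
            for r in rows:
                report_rows.append(
                    {
                        "candidate_gene": r.gene_id,
                        "scaffold": r.contig,
                        "annotation": r.annotation,
                        "zhp": r.zhp,
                        "di": r.di,
                        "population": config.populations[p],
                    }
                )
    counts["loci_called"] = len(loci_rows)
    loci_path = out_dir / "selected_loci.bed"
    with open(loci_path, "w") as fh:
        for row in loci_rows:
            fh.write(
                f"{row['contig']}\t{row['start']}\t{row['end']}\t"
                f"{row['population']}\t0\t.\n"
            )
    outputs["loci"] = str(loci_path)
    report_path = out_dir / "candidate_genes.tsv"
    pd.DataFrame(
        report_rows,
        columns=["candidate_gene", "scaffold", "annotation", "zhp", "di", "population"],
    ).to_csv(report_path, sep="\t", index=False)
    outputs["candidate_genes"] = str(report_path)

    # conservation screen over selected genes, per target population
    cons_rows = []
    if genes and config.alignments_dir:
        selected_gene_ids = {
            r["candidate_gene"]: r["population"] for r in report_rows
        }
        aln_dir = Path(config.alignments_dir)
        pop_index = {name: i for i, name in enumerate(config.populations)}
        for gene_id, pop_name in selected_gene_ids.items():
            path = aln_dir / f"{gene_id}.fa"
            if not path.exists():
                logger.warning("no alignment for selected gene %s", gene_id)
                continue
            aln = read_alignment_fasta(str(path))
            conserved = find_conserved_sites(aln)
            gene_models = [g for g in genes if g.gene_id == gene_id]
            regions = gene_flank_regions(gene_models, config.flank, contig_lengths)
            focal = pop_index[pop_name]
            specific = breed_specific_snvs(
                kept,
                focal,
                presence_min=config.presence_min,
                absence_max=config.absence_max,
                regions=regions,
            )
            for r in intersect_and_classify(specific, conserved, gene_models, focal):
                cons_rows.append(
                    {
                        "gene": r.gene_id,
                        "contig": r.contig,
                        "pos": r.pos,
                        "population": pop_name,
                        "ref": r.ref,
                        "alt": r.alt,
                        "conserved": "y",
                        "coding": "y" if r.coding else "n",
                    }
                )
    cons_path = out_dir / "conserved_specific_snvs.tsv"
    pd.DataFrame(
        cons_rows,
        columns=["gene", "contig", "pos", "population", "ref", "alt", "conserved", "coding"],
    ).to_csv(cons_path, sep="\t", index=False)
    outputs["conserved_specific"] = str(cons_path)
    counts["conserved_specific_snvs"] = len(cons_rows)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "counts": counts,
        "outputs": outputs,
        "seed": config.seed,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
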