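"""Synthetic pool-seq data with known differentiation and planted sweeps.

Population allele frequencies follow a Balding–Nichols style model: per
site an ancestral frequency p is drawn uniformly, and each population's
frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so F sets the background
differentiation. Sweeps push target-population frequencies toward
fixation inside chosen intervals, jointly depressing windowed
heterozygosity and inflating pairwise differentiation there. Read
counts per pool are Poisson total depth with binomial alternate reads.

:func:`write_fixture_bundle` emits a complete text fixture: a pooled
VCF, a toy GFF3 with genes inside and outside the sweeps, per-gene
multi-species alignments with planted conserved columns and planted
breed-specific variants, and machine-readable truth files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import PooledVariant, write_pooled_vcf

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SweepSpec:
    """A half-open interval pushed toward fixation in target populations.

    ``fixation_push`` moves each target-population frequency f to
    ``f + push * (nearest(f) - f)`` where nearest(f) is 0 for f < 0.5
    and 1 otherwise.
    """

    contig: str
    start: int
    end: int
    target_populations: tuple[int, ...]
    fixation_push: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigError("sweep end must exceed start")
        if not 0.0 <= self.fixation_push <= 1.0:
            raise ConfigError("fixation_push must lie in [0, 1]")
        if not self.target_populations:
            raise ConfigError("sweep needs at least one target population")


@dataclass(frozen=True)
class SimulationConfig:
    n_populations: int = 6
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"contig1": 2_000_000}
    )
    snv_density: float = 0.005
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    drift_F: float = 0.05
    mean_depth: float = 12.0
    sweep_specs: tuple[SweepSpec, ...] = ()
    seed: int = 0
    population_names: tuple[str, ...] | None = None
    low_qual_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_populations < 2:
            raise ConfigError("need at least 2 populations")
        if not 0.0 < self.drift_F < 1.0:
            raise ConfigError("drift_F must lie strictly in (0, 1)")
        if self.mean_depth < 1:
            raise ConfigError("mean_depth must be >= 1")
        if not self.contig_lengths:
            raise ConfigError("no contigs configured")
        lo, hi = self.ancestral_freq_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigError("ancestral_freq_range must satisfy 0 <= low < high <= 1")
        if not 0.0 <= self.low_qual_fraction <= 1.0:
            raise ConfigError("low_qual_fraction must lie in [0, 1]")
        for spec in self.sweep_specs:
            if spec.contig not in self.contig_lengths:
                raise ConfigError(f"sweep on unknown contig {spec.contig!r}")
            if spec.end > self.contig_lengths[spec.contig]:
                raise ConfigError("sweep region extends past contig end")
            if max(spec.target_populations) >= self.n_populations:
                raise ConfigError("sweep targets a population index out of range")

    @property
    def names(self) -> list[str]:
        if self.population_names is not None:
            if len(self.population_names) != self.n_populations:
                raise ConfigError("population_names length mismatch")
            return list(self.population_names)
        return [f"pop{i}" for i in range(self.n_populations)]

    def freq_columns(self) -> list[str]:
        return [f"freq_{name}" for name in self.names]


def simulate_population_frequencies(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-site ancestral and per-population allele frequencies.

    Returns a frame with columns ``contig, pos, ref, alt, anc_freq`` and
    one ``freq_<population>`` column per pool. ``pos`` is 1-based.
    Deterministic for a fixed config (seeded internally).
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    lo, hi = config.ancestral_freq_range
    F = config.drift_F
    scale = (1.0 - F) / F
    for contig, length in config.contig_lengths.items():
        n = int(round(length * config.snv_density))
        n = min(n, length)
        pos0 = np.sort(rng.choice(length, size=n, replace=False))
        anc = rng.uniform(lo, hi, size=n)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        cols = {
            "contig": np.repeat(contig, n),
            "pos": pos0 + 1,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "anc_freq": anc,
        }
        a = anc * scale
        b = (1.0 - anc) * scale
        for col in config.freq_columns():
            cols[col] = rng.beta(a, b)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def plant_sweeps(
    freq_table: pd.DataFrame, sweep_specs: Sequence[SweepSpec]
) -> pd.DataFrame:
    """Push target-population frequencies toward fixation inside sweeps.

    Outside sweep intervals, and for non-target populations, the table
    is unchanged. Overlapping sweeps with different target sets are
    rejected.
    """
    specs = list(sweep_specs)
    for i, s in enumerate(specs):
        for t in specs[i + 1 :]:
            if (
                s.contig == t.contig
                and s.start < t.end
                and t.start < s.end
                and set(s.target_populations) != set(t.target_populations)
            ):
                raise ConfigError(
                    f"overlapping sweeps with conflicting targets: {s} vs {t}"
                )
    out = freq_table.copy()
    freq_cols = [c for c in out.columns if c.startswith("freq_")]
    pos0 = out["pos"].to_numpy() - 1
    for spec in specs:
        mask = (
            (out["contig"].to_numpy() == spec.contig)
            & (pos0 >= spec.start)
            & (pos0 < spec.end)
        )
        if not mask.any():
            continue
        for pop in spec.target_populations:
            col = freq_cols[pop]
            f = out.loc[mask, col].to_numpy()
            target = np.where(f < 0.5, 0.0, 1.0)
            out.loc[mask, col] = f + spec.fixation_push * (target - f)
    return out


def sample_pooled_reads(
    freq_table: pd.DataFrame,
    mean_depth: float,
    seed: int,
    low_qual_fraction: float = 0.05,
) -> list[PooledVariant]:
    """Draw pooled read counts: Poisson depths, binomial alternate reads.

    Sites where no pool samples a single alternate read are dropped (a
    caller would never emit them). QUAL values are integers, a
    ``low_qual_fraction`` share drawn below 30 to exercise the quality
    filter.
    """
    if mean_depth < 1:
        raise ConfigError("mean_depth must be >= 1")
    rng = np.random.default_rng(seed)
    freq_cols = [c for c in freq_table.columns if c.startswith("freq_")]
    n_sites = len(freq_table)
    n_pops = len(freq_cols)
    freqs = freq_table[freq_cols].to_numpy()
    depth = rng.poisson(mean_depth, size=(n_sites, n_pops))
    alt = rng.binomial(depth, freqs)
    ref = depth - alt
    low = rng.random(n_sites) < low_qual_fraction
    qual = np.where(
        low, rng.integers(10, 30, size=n_sites), rng.integers(30, 100, size=n_sites)
    ).astype(float)
    keep = alt.sum(axis=1) > 0
    contigs = freq_table["contig"].to_numpy()
    positions = freq_table["pos"].to_numpy()
    refs = freq_table["ref"].to_numpy()
    alts = freq_table["alt"].to_numpy()
    variants = []
    ref_l = ref.tolist()
    alt_l = alt.tolist()
    for i in np.flatnonzero(keep):
        variants.append(
            PooledVariant(
                contig=str(contigs[i]),
                pos=int(positions[i]),
                ref=str(refs[i]),
                alt=str(alts[i]),
                qual=float(qual[i]),
                counts=tuple(zip(ref_l[i], alt_l[i])),
            )
        )
    return variants


# ---------------------------------------------------------------------------
# fixture bundle


@dataclass
class FixtureBundle:
    vcf: Path
    gff: Path
    alignments_dir: Path
    alignment_paths: dict[str, Path]
    truth_bed: Path
    truth_json: Path
    truth: dict


def _place_genes(
    config: SimulationConfig, gene_length: int, n_background: int
) -> list[dict]:
    """One gene centred in each sweep plus background genes clear of sweeps."""
    genes = []
    counter = 1
    for spec in config.sweep_specs:
        mid = (spec.start + spec.end) // 2
        gs = max(0, mid - gene_length // 2)
        ge = min(config.contig_lengths[spec.contig], gs + gene_length)
        genes.append(
            {
                "gene_id": f"gene_{counter:04d}",
                "contig": spec.contig,
                "start": gs,
                "end": ge,
                "in_sweep": True,
                "target_population": spec.target_populations[0],
            }
        )
        counter += 1
    placed = 0
    for contig, length in config.contig_lengths.items():
        if placed >= n_background:
            break
        step = max(gene_length + 2000, length // (n_background + 1))
        for gs in range(step // 2, length - gene_length, step):
            ge = gs + gene_length
            clash = any(
                s.contig == contig and gs - 2000 < s.end and s.start < ge + 2000
                for s in config.sweep_specs
            ) or any(
                g["contig"] == contig and gs < g["end"] + 2000 and g["start"] - 2000 < ge
                for g in genes
            )
            if clash:
                continue
            genes.append(
                {
                    "gene_id": f"gene_{counter:04d}",
                    "contig": contig,
                    "start": gs,
                    "end": ge,
                    "in_sweep": False,
                    "target_population": None,
                }
            )
            counter += 1
            placed += 1
            if placed >= n_background:
                break
    return genes


def _cds_intervals(gs: int, ge: int) -> list[tuple[int, int]]:
    """Two CDS exons at fixed offsets within the gene (0-based half-open)."""
    length = ge - gs
    e1 = (gs + min(200, length // 8), gs + min(600, length // 3))
    e2 = (gs + min(900, length // 2), gs + min(1300, 2 * length // 3))
    return [e1, e2]


def _write_gff(path: Path, genes: list[dict]) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        gid = g["gene_id"]
        s1, e1 = g["start"] + 1, g["end"]  # GFF3 is 1-based inclusive
        lines.append(
            f"{g['contig']}\tpoolsweep\tgene\t{s1}\t{e1}\t.\t+\t.\t"
            f"ID={gid};Name={gid.upper()}"
        )
        lines.append(
            f"{g['contig']}\tpoolsweep\tmRNA\t{s1}\t{e1}\t.\t+\t.\t"
            f"ID={gid}.t1;Parent={gid}"
        )
        for k, (cs, ce) in enumerate(_cds_intervals(g["start"], g["end"]), start=1):
            lines.append(
                f"{g['contig']}\tpoolsweep\tCDS\t{cs + 1}\t{ce}\t.\t+\t0\t"
                f"ID={gid}.cds{k};Parent={gid}.t1"
            )
    path.write_text("\n".join(lines) + "\n")


def _build_alignment(
    rng: np.random.Generator,
    gene: dict,
    ref_seq: dict[int, str],
    conserved_pos: list[int],
    n_species: int,
) -> tuple[list[str], list[str], list[int]]:
    """Aligned rows for one gene; returns (names, rows, insert_columns)."""
    gs, ge = gene["start"], gene["end"]
    positions = list(range(gs, ge))
    conserved = set(conserved_pos)
    names = [f"reference|{gene['gene_id']}"] + [
        f"species{k:02d}" for k in range(1, n_species)
    ]
    columns: list[list[str]] = []
    insert_before = set(
        rng.choice(np.arange(1, len(positions) - 1), size=2, replace=False).tolist()
    )
    insert_columns: list[int] = []
    for col_idx, pos in enumerate(positions):
        if col_idx in insert_before:
            # insertion relative to the reference: reference row gaps
            base = str(_BASES[rng.integers(0, 4)])
            col = ["-"] + [base] * (n_species - 1)
            mutated = int(rng.integers(1, n_species))
            col[mutated] = str(_BASES[(np.flatnonzero(_BASES == base)[0] + 1) % 4])
            insert_columns.append(len(columns))
            columns.append(col)
        base = ref_seq[pos]
        if pos in conserved:
            columns.append([base] * n_species)
        else:
            col = [base] * n_species
            k = int(rng.integers(1, 4))
            rows_to_mutate = rng.choice(
                np.arange(1, n_species), size=min(k, n_species - 1), replace=False
            )
            for r in rows_to_mutate:
                shift = int(rng.integers(1, 4))
                col[r] = str(_BASES[(np.flatnonzero(_BASES == base)[0] + shift) % 4])
            if rng.random() < 0.1:
                col[int(rng.integers(1, n_species))] = "-"
            columns.append(col)
    rows = ["".join(col[r] for col in columns) for r in range(n_species)]
    return names, rows, insert_columns


def write_fixture_bundle(
    config: SimulationConfig,
    out_dir: str | Path,
    gene_length: int = 1800,
    n_background_genes: int = 4,
    n_species: int = 12,
    conserved_fraction: float = 0.3,
) -> FixtureBundle:
    """Generate and write a full text fixture; see module docstring.

    Per sweep gene, two breed-specific SNVs are planted at conserved
    positions (one inside a CDS exon, one outside) plus one at a
    non-conserved position; truth files record everything planted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aln_dir = out_dir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    freq = simulate_population_frequencies(config)
    freq = plant_sweeps(freq, config.sweep_specs)
    genes = _place_genes(config, gene_length, n_background_genes)

    # plant breed-specific variants in sweep genes
    planted = []
    freq_cols = config.freq_columns()
    extra_rows = []
    drop_pos: set[tuple[str, int]] = set()
    for g in genes:
        if not g["in_sweep"]:
            continue
        cds = _cds_intervals(g["start"], g["end"])
        pos_cds = (cds[0][0] + cds[0][1]) // 2
        pos_nc = (cds[0][1] + cds[1][0]) // 2  # intronic: between the exons
        pos_plain = min(g["end"] - 50, cds[1][1] + 150)  # not conserved
        focal = g["target_population"]
        for pos0, conserved, label in (
            (pos_cds, True, "cds"),
            (pos_nc, True, "noncoding"),
            (pos_plain, False, "nonconserved"),
        ):
            drop_pos.add((g["contig"], pos0 + 1))
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + int(rng.integers(1, 4))) % 4
            row = {
                "contig": g["contig"],
                "pos": pos0 + 1,
                "ref": str(_BASES[ref_i]),
                "alt": str(_BASES[alt_i]),
                "anc_freq": 0.5,
            }
            for k, col in enumerate(freq_cols):
                row[col] = 1.0 if k == focal else 0.0
            extra_rows.append(row)
            planted.append(
                {
                    "gene_id": g["gene_id"],
                    "contig": g["contig"],
                    "pos": pos0 + 1,
                    "population": int(focal),
                    "conserved": conserved,
                    "coding": label == "cds",
                    "label": label,
                }
            )
    if drop_pos:
        mask = ~freq.apply(
            lambda r: (r["contig"], int(r["pos"])) in drop_pos, axis=1
        )
        freq = freq[mask]
    if extra_rows:
        freq = pd.concat([freq, pd.DataFrame(extra_rows)], ignore_index=True)
    freq = freq.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)

    variants = sample_pooled_reads(
        freq, config.mean_depth, seed=config.seed + 1, low_qual_fraction=config.low_qual_fraction
    )

    vcf_path = out_dir / "variants.vcf"
    write_pooled_vcf(variants, str(vcf_path), config.names, config.contig_lengths)

    gff_path = out_dir / "genes.gff3"
    _write_gff(gff_path, genes)

    # per-gene alignments with planted conserved columns
    variant_pos = {(c, int(p)) for c, p in zip(freq["contig"], freq["pos"])}
    planted_by_gene: dict[str, list[dict]] = {}
    for p in planted:
        planted_by_gene.setdefault(p["gene_id"], []).append(p)
    ref_base = {
        (c, int(p)): b for c, p, b in zip(freq["contig"], freq["pos"], freq["ref"])
    }
    alignment_paths: dict[str, Path] = {}
    truth_conserved: dict[str, list[int]] = {}
    for g in genes:
        gs, ge = g["start"], g["end"]
        contig = g["contig"]
        seq = {
            pos: ref_base.get((contig, pos + 1), str(_BASES[rng.integers(0, 4)]))
            for pos in range(gs, ge)
        }
        candidates = [
            pos for pos in range(gs, ge) if (contig, pos + 1) not in variant_pos
        ]
        n_cons = max(1, int(len(candidates) * conserved_fraction))
        conserved_pos = sorted(
            rng.choice(np.asarray(candidates), size=n_cons, replace=False).tolist()
        )
        for p in planted_by_gene.get(g["gene_id"], []):
            pos0 = p["pos"] - 1
            if p["conserved"] and pos0 not in conserved_pos:
                conserved_pos.append(pos0)
            if not p["conserved"] and pos0 in conserved_pos:
                conserved_pos.remove(pos0)
        conserved_pos.sort()
        names, rows, _ = _build_alignment(rng, g, seq, conserved_pos, n_species)
        path = aln_dir / f"{g['gene_id']}.fa"
        with open(path, "w") as fh:
            for k, (name, row) in enumerate(zip(names, rows)):
                if k == 0:
                    fh.write(f">{name} loc={contig}:{gs}\n")
                else:
                    fh.write(f">{name}\n")
                fh.write(row + "\n")
        alignment_paths[g["gene_id"]] = path
        truth_conserved[g["gene_id"]] = conserved_pos

    bed_path = out_dir / "truth_sweeps.bed"
    names = config.names
    with open(bed_path, "w") as fh:
        for spec in config.sweep_specs:
            label = ",".join(names[i] for i in spec.target_populations)
            fh.write(
                f"{spec.contig}\t{spec.start}\t{spec.end}\t{label}\t0\t+\n"
            )

    truth = {
        "config": {
            "n_populations": config.n_populations,
            "contig_lengths": dict(config.contig_lengths),
            "snv_density": config.snv_density,
            "drift_F": config.drift_F,
            "mean_depth": config.mean_depth,
            "seed": config.seed,
            "population_names": names,
        },
        "n_sites_simulated": int(len(freq)),
        "n_polymorphic": int(len(variants)),
        "sweeps": [asdict(s) for s in config.sweep_specs],
        "genes": genes,
        "planted_specific_snvs": planted,
        "conserved_positions": truth_conserved,
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, default=str))

    return FixtureBundle(
        vcf=vcf_path,
        gff=gff_path,
        alignments_dir=aln_dir,
        alignment_paths=alignment_paths,
        truth_bed=bed_path,
        truth_json=truth_path,
        truth=truth,
    )
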