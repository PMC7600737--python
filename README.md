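# poolsweep

Selection-signature scanning for pooled whole-genome sequencing
(pool-seq) data, plus a synthetic-data generator for end-to-end testing.

Given a multi-pool VCF (one sample per population, per-site allele read
depths in `AD`), the pipeline:

1. **filters SNVs** — biallelic only, QUAL ≥ 30, summed coverage ≥ 68,
   ≥ 3 alternate reads (all configurable);
2. **computes pooled heterozygosity** Hp = 2·ΣnMaj·ΣnMin/(ΣnMaj+ΣnMin)²
   in sliding windows (50 kb / 25 kb step by default) and Z-transforms it
   per population (**ZHp**), keeping only windows with > 10 SNVs;
3. **computes pairwise Fst** per window from a mean-squares (ANOVA)
   estimator on read counts, and the per-population **di** score
   (sum of genome-standardised pairwise Fst over all other populations);
4. **calls selected loci** as windows with ZHp < −7 *and* di above the
   genome-wide top-1% cutoff, merges them, and annotates overlapping
   genes from a GFF3;
5. **screens breed-specific SNVs** in selected genes (± 1000 bp) against
   conserved columns of per-gene multi-species alignments, labelling hits
   coding/non-coding via CDS features.

The `poolsweep.simulate` module generates complete text fixtures
(VCF + GFF3 + alignments + truth files) with known background
differentiation (Balding–Nichols drift) and planted sweeps, so every
stage is testable without external data.

## CLI

```bash
# generate a synthetic fixture bundle
poolsweep simulate --out-dir demo --seed 1 --n-populations 6 \
    --n-contigs 2 --contig-length 2000000 --n-sweeps 2

# full scan (flags override the YAML config)
poolsweep scan --vcf demo/variants.vcf --gff demo/genes.gff3 \
    --alignments-dir demo/alignments \
    --populations pop0,pop1,pop2,pop3,pop4,pop5 --out-dir demo_out

# stage subcommands
poolsweep filter --vcf in.vcf --populations a,b,c --out filtered.vcf
poolsweep zhp --vcf filtered.vcf --populations a,b,c --out zhp.tsv
poolsweep di  --vcf filtered.vcf --populations a,b,c --out di.tsv
poolsweep validate --config run.yaml
```

`scan` writes per-window ZHp/Fst/di TSVs, a BED of called loci, a
candidate-gene report (gene, scaffold, annotation, ZHp, di), the
conserved breed-specific SNV report, and a JSON manifest with per-stage
counts. Exit codes: 0 ok, 1 config error, 2 runtime error.

## Library use

```python
from poolsweep import (
    read_pooled_vcf, filter_variants, make_windows, z_transform,
    per_snv_fst, compute_di, RunConfig, run_full_scan,
)
```

See module docstrings in `src/poolsweep/` for the estimator definitions
and conventions (read counts treated as sampled alleles; windows are
0-based half-open; VCF positions 1-based).

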