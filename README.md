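# karstpop

Population-genomic statistics for small, highly inbred populations, built
around a four-population design (one target population, two background
populations, one outgroup).  The package implements:

- **io_core** — VCF / GFF3 / conservation-score-track / popmap ingestion,
  biallelic-SNP and missingness filters, and pipe-delimited effect-annotation
  parsing (effect term → coding class via a fixed, versioned mapping).
- **simulate** — a seeded synthetic-data generator emitting a complete file
  bundle (VCF, GFF3, score track, popmap, callability table, truth JSON)
  with controllable inbreeding (planted runs of homozygosity), deleterious-
  allele placement, migration, sweep regions, and codon-consistent effect
  annotations.  Same config + seed → byte-identical files.
- **diversity** — per-site and windowed nucleotide diversity (fixed-size
  window denominator), heterozygosity per kb (overall and coding vs
  non-coding), non-synonymous/synonymous ratios, and kinship coefficients
  with degree classification.
- **roh** — run-of-homozygosity detection with 20-SNP sliding-window rules
  (≤ 1 het per window, 5% window hit threshold, 50-SNP / 100-kb / density /
  gap segment filters), genome and per-chromosome f_ROH, gene-overlap
  fractions, and the excess-homozygosity inbreeding coefficient F.
- **load** — outgroup polarization, the shared-monomorphic-site filter,
  masked vs realized conservation-score load (score threshold 4), effect-
  category genotype proportions (all-genotypes and homozygous-only modes),
  and one-way ANOVA with pairwise contrasts.
- **geneflow** — frequency-weighted ABBA-BABA D-statistics with
  delete-one-block jackknife standard errors and Z scores.
- **selection** — sliding-window diversity log-ratio scans, EHH / iHH /
  XP-EHH with genome-wide Z-transformation and top-5% outliers, NG86 Ka/Ks
  with Jukes-Cantor correction, the ≥ 2-method sweep consensus, and
  private / fixed non-synonymous and premature-stop variant screens.

## CLI

A `karstpop` console script groups the pipeline stages:

```sh
# generate a synthetic bundle
karstpop simulate --config sim.yaml --out bundle/

# validate inputs
karstpop validate --vcf bundle/data.vcf --popmap bundle/popmap.tsv \
    --gerp bundle/gerp.tsv --gff bundle/genes.gff3

# analyses
karstpop diversity --vcf … --popmap … --gff … --callable … --out div.tsv
karstpop roh       --vcf … --popmap … --genome-length 1000000 --out roh/
karstpop load      --vcf … --popmap … --gerp … --threshold 4 --out load.tsv
karstpop dstat     --vcf … --popmap … --quartet P1,P2,P3,O --out dstat.tsv
karstpop selection --vcf … --popmap … --gff … --candidate-pop target \
    --reference-pop backgroundA --out sweep.tsv
karstpop screen    --vcf … --popmap … --target-pop target --mode fixed \
    --max-bg-freq 0.2895 --out screen.tsv
```

A minimal simulation config:

```yaml
seed: 1
genome: [[chr1, 1000000]]
mutation_density: 3.0     # SNPs per kb
f_roh: {target: 0.5}
migration: 0.0
n_genes: 30
```

## Conventions

- Genotype codes: 0 = hom-ref, 1 = het, 2 = hom-alt, −1 = missing.
- Coordinates are 1-based inclusive at the VCF boundary; all internal
  intervals (genes, windows, planted segments) are half-open 0-based.
- Derived alleles are polarized by the outgroup; sites where the outgroup
  is heterozygous, missing, or polymorphic are excluded from polarized
  analyses.
- Diversity-ratio scans put the candidate population in the denominator,
  so selective sweeps in the candidate give large positive values.
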