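# prsphewas

A tested pipeline for polygenic-score phenome-wide association analysis:

- **`genio`** — VCF (DS/GT) and dosage-TSV readers, variant QC (MAF,
  missingness, exact Hardy–Weinberg test, imputation quality), weight-file
  harmonization (allele swap / strand flip / ambiguous-SNP handling),
  GFF3/BED gene models and GMT pathway sets.
- **`scoring`** — raw and standardized polygenic scores with mean-impute or
  omit missing-dosage policies, plus variant-subset restriction.
- **`phewas`** — linear-model association of each standardized score with
  each phenotype/wave (covariates: sex, age at measurement, 10 PCs), the
  Δadjusted-R² effect measure (percent scale), Benjamini–Hochberg q-values
  within per-score families, score validation/retention, and before/after
  sensitivity-run comparison.
- **`interaction`** — score×sex moderation with a naive model and a robust
  model that adds every covariate×score and covariate×sex product term;
  conjunction flagging (both q's < 0.05).
- **`trends`** — association strength (ΔadjR²) as a smooth function of mean
  participant age: natural cubic spline with 3 df (2 df at exactly 3 time
  points), nested F-ratio tests for the linear and non-linear components,
  and individual-level bootstrap confidence bands.
- **`pathways`** — partition eligibility (>1 % variance explained and
  q < 0.05 hits in every phenotype category), SNP→gene mapping within
  ±100 kb, hypergeometric pathway over-representation (BH, q < 0.01),
  pathway-restricted scores and their full re-scan.
- **`synthetic_data`** — seeded generator for genotypes in Hardy–Weinberg
  proportions, sparse weights (optionally concentrated in a planted
  pathway), longitudinal phenotypes with a configured variance-explained
  trajectory, and a toy genome written as GFF3/BED + GMT.
- **`cli`** — the `prsphewas` command chaining all stages from a YAML
  config.

## CLI

Generate a synthetic fixture and run the full pipeline:

```sh
prsphewas simulate --out fixture --seed 7 --n-samples 1000 --n-variants 300 \
    --ages 16,20,24 --planted-pathway planted --n-null-phenotypes 8

prsphewas all --config run.yaml
```

`run.yaml` names the inputs and thresholds:

```yaml
seed: 7
outdir: run1
alpha: 0.05          # PheWAS q-value threshold
enrich_alpha: 0.01   # pathway enrichment q threshold
window_bp: 100000    # SNP-to-gene window
min_delta_pct: 1.0   # partition eligibility floor (percent adjR2)
inputs:
  genotypes: fixture/genotypes.tsv
  variants: fixture/variants.tsv     # optional sidecar for the TSV dialect
  genotype_format: tsv               # or vcf
  weights: fixture/weights.tsv
  samples: fixture/samples.tsv
  measurements: fixture/measurements.tsv
  phenotype_meta: fixture/phenotype_meta.tsv
  genes: fixture/genes.gff3
  gmt: fixture/pathways.gmt
qc: {min_maf: 0.01, max_missing: 0.05, min_hwe_p: 5.0e-7, min_info_r2: 0.3}
validation: {weights: phen1}         # score name -> validation phenotype
```

Subcommands `qc`, `score`, `validate`, `phewas`, `interact`, `trends`,
`pathways` run the pipeline up to and including that stage. Every stage
writes plain TSV/JSON into `outdir`, including a `run_log.json` with the
seed and config hash; reruns with the same config and seed are
bit-identical.

### File formats

- **Dosage TSV dialect**: header row `sample_id` + variant ids, one row per
  sample, `NA` for missing. An optional sidecar `variants.tsv`
  (`variant_id, chrom, pos, allele_a1, allele_a2[, info_r2]`) supplies
  coordinates and alleles, which harmonization requires.
- **Weight TSV**: `variant_id, chrom, pos, effect_allele, other_allele,
  weight`.
- **Phenotypes**: `samples.tsv` (`sample_id, sex, pc1..pc10`),
  `measurements.tsv` (long-format `sample_id, phenotype, wave, age, value`),
  `phenotype_meta.tsv` (`phenotype, category, is_age_of_initiation`).

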