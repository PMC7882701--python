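# ddgeval

Evaluate protein stability perturbation (|ΔΔG|, kcal/mol) as a missense
pathogenicity signal, stratified by gene inheritance mode.

The package takes a tabular variant file (one row per missense variant:
gene, pathogenic/benign label, per-predictor ΔΔG values) plus plain-text
gene lists for haploinsufficient / autosomal-dominant / autosomal-recessive
genes, and computes:

- **Predictor ranking** — AUC of each predictor's |ΔΔG| scores, averaged
  over repeated class-balanced subsets (all minority-class variants matched
  with an equal-size random benign subset, 100× by default).
- **Consensus scores** — mean-of-|ΔΔG| pseudo-predictors over any subset of
  the panel (e.g. the best two tools), plus combination enumeration.
- **Inheritance-mode stratification** — balanced AUC per gene group
  (haploinsufficient, dominant-without-HI, recessive) and its complement,
  with a Mann-Whitney U comparison of per-gene AUC distributions.
- **Precision–threshold enrichment** — precision (PPV) of "|ΔΔG| ≥ t ⇒
  pathogenic" over a threshold grid, and the smallest threshold reaching a
  target precision with adequate support.
- **Destabilizing-only variants** of the above (records each predictor
  calls harmonized ΔΔG > 0).
- A **synthetic data generator** with class-conditional |ΔΔG| laws,
  mode-specific effect sizes, correlated noisy predictors, sign
  conventions, output caps and missingness — so the whole pipeline is
  testable without any external download. `emulate_paper_shape` produces a
  fixture with the upstream dataset's exact marginal counts (13,508
  variants, 3,338/10,170 pathogenic/benign, 100 genes).

Predictor sign conventions differ between tools; datasets are harmonized
once (all predictors become positive-destabilizing) before signed analyses.
A default, editable convention/cap map for 13 common tools ships in
`src/ddgeval/conventions.yaml`.

## CLI

All commands take a YAML run config (see below), with `--seed`, `--out`,
`--reps`, `--predictors` and `--balanced/--unbalanced-precision` overrides:

```sh
ddgeval simulate  --config config.yaml --out simdir     # write synthetic inputs
ddgeval evaluate  --config config.yaml --seed 1          # full pipeline + figures
ddgeval precision --config config.yaml --out out/        # precision curves only
ddgeval compare   --config config.yaml --out out/        # group tests only
ddgeval report    --bundle out/ --fmt png                # figures from a bundle
```

Exit codes: 0 ok, 2 config error, 3 data error, 4 undefined stratum.

A run config names exactly one input source — real files:

```yaml
input:
  variant_table: variants.tsv
  column_map:
    variant_id: id
    gene: gene
    label: clinvar_label
    predictors: {foldx5: FoldX, inps3d: INPS3D}
  gene_lists: {hi: hi.txt, ad: ad.txt, ar: ar.txt}
  conventions: my_conventions.yaml   # optional; defaults shipped
```

or a synthetic one:

```yaml
synthetic:
  n_genes_by_mode: {hi: 10, ad_only: 10, ar: 10, unlisted: 10}
  variants_per_gene: 30
  pathogenic_fraction: 0.3
  benign_law: {family: gamma, shape: 1.0, scale: 1.0}
  delta_by_mode: {hi: 2.0, ad_only: 0.5, ar: 0.5, unlisted: 0.5}
  predictors:
    - {name: a, noise_sd: 0.5}
    - {name: b, noise_sd: 1.0, sign: neg, cap: 5.0, missing_rate: 0.05}
  stabilizing_prob: 0.05
consensus:
  - {members: [a, b], output_name: mean_ab}
evaluation: {n_reps: 100, seed: 1, threshold_step: 0.1,
             precision_targets: [0.9, 0.96], min_support: 10}
outdir: out
```

`ddgeval evaluate` writes TSV tables (ranking, group comparison, precision
curves and thresholds, destabilizing-only variants of each), SVG figures
and a YAML manifest; re-running the same config reproduces every table
byte-identically.

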