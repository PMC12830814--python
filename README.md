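# metaprs

Meta polygenic risk scores (metaPRS) for binary disease outcomes, built
around a fully synthetic, ground-truth-known cohort generator so every
stage is testable without external genotype data.

The package implements an end-to-end analysis pipeline:

1. **Synthetic cohort generation** (`metaprs.synthetic`) — independent-variant
   genotype dosages, nine component-trait scoring files (disease,
   inflammation markers, lipids) with configurable allele swaps and strand
   flips, covariates, platform labels, an optional platform batch artefact,
   and a logistic-model binary outcome.
2. **Genotype QC** (`metaprs.qc`) — variant filters (call rate, MAF, exact
   Hardy–Weinberg test, strand-ambiguous and multi-allelic flags), sample
   filters (call rate, method-of-moments pi-hat), EIGENSTRAT-style
   principal components, and cross-platform harmonization (per-variant
   logistic association of platform on dosage adjusted for PCs; variants
   with Wald p < 5e-8 removed).
3. **PRS scoring** (`metaprs.scoring`) — PGS-Catalog-format scoring-file
   parsing, allele harmonization (direct / allele swap / strand complement,
   ambiguous records dropped), dosage-weighted score computation with
   mean imputation of missing dosages, and standardization.
4. **Meta-score construction** (`metaprs.meta`, `metaprs.elasticnet`) —
   elastic-net logistic regression of the outcome on standardized component
   scores (confounders unpenalized), grid selection by ten-fold
   cross-validated AUC, and the weighted-average combination
   `meta_i = sum_k beta_k Z_ik / sum_k beta_k` with inflammation
   (T2D, IL-1ra, IL-6, IL-8, TNF-R1, CRP) and lipids (T2D, LDL-C, HDL-C,
   TG) presets.
5. **Association models** (`metaprs.epi`) — quintile (Q3 reference) and
   per-SD odds ratios, plus the five nested prediction models (base
   covariates; + clinical covariates; + one of the three scores).
6. **Discrimination statistics** (`metaprs.discrimination`) — AUC with
   DeLong variance, the paired DeLong test, Nagelkerke pseudo-R²,
   continuous (category-free) NRI with seeded bootstrap CIs, and an
   assembled per-model report.
7. **Pipeline** (`metaprs.pipeline`) — simulate → QC → score → 70/30 split
   → train meta models → apply frozen models to the validation subset →
   association tables → discrimination report, with deterministic,
   hash-stamped artifacts.

## CLI

```bash
metaprs simulate --n-individuals 2000 --n-variants 500 --seed 1 --out sim/
metaprs qc --dosages sim/dosages.tsv --covariates sim/covariates.tsv \
    --preset cnics --out qc/
metaprs score --dosages qc/dosages_filtered.tsv \
    --scoring-file sim/score_T2D.txt --out scores.tsv
metaprs train-meta --z z.tsv --covariates cov.tsv --preset inflammation \
    --out model.json
metaprs apply-meta --z z_new.tsv --model model.json --out meta.tsv
metaprs associate --data data.tsv --score-col score_t2d --out table2.tsv
metaprs evaluate --data data.tsv --n-boot 1000 --seed 1 --out report/
metaprs run --config pipeline.yaml --out run/
```

QC presets: `cnics` (call rate ≥ 0.95, MAF ≥ 0.01, HWE p ≥ 1e-5, sample
call rate ≥ 0.90, pi-hat ≤ 0.9, platform p < 5e-8), `regards1` (call rate
≥ 0.90, HWE p ≥ 1e-12), `regards2` (call rate ≥ 0.95, HWE p ≥ 1e-5,
sample call rate ≥ 0.98).

A pipeline config (YAML or JSON) mirrors `PipelineConfig`:

```yaml
sim:
  n_individuals: 2000
  n_variants: 300
  seed: 1
  trait_effects: [0.5, 0.1, 0, 0, 0, 0, 0.2, -0.1, 0.1]
qc_preset: cnics
enet: {l1_grid: [0.5, 1.0], path_length: 8, n_folds: 10}
split_fraction: 0.70
n_boot: 200
```

## Design notes and limitations

- Variants are simulated without linkage disequilibrium; scores and QC
  contracts do not depend on LD structure.
- The outcome is generated from a logistic (not liability-probit) model so
  generative per-SD log-odds are directly recoverable by logistic
  regression.
- Standardization uses the n−1 SD convention; component scores are
  standardized within each evaluation cohort by default.
- HWE and pi-hat operate on hard-called genotypes (dosages rounded;
  entries > 0.1 from an integer treated as missing for those tests only).
- All randomness is driven by explicit seeds; identical configs reproduce
  byte-identical artifacts.
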