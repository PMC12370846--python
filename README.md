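# mrchain

Summary-data Mendelian randomization (MR) along causal chains: a
three-stage pipeline for screening candidate exposures against an
outcome, validating hits with SMR + HEIDI, and decomposing effects
through mediators with two-step mediation MR. Everything runs on GWAS
summary statistics (plain tab-separated text) plus an LD reference
matrix; a built-in simulator generates complete studies with known
ground truth so the whole pipeline is testable offline.

## What it implements

- **Harmonization** (`mrchain.sumstats`) — exposure/outcome allele
  alignment with strand complementation, palindromic-SNP resolution by
  allele frequency (ambiguity window ±0.08 around 0.5), and removal of
  incompatible allele sets.
- **Instrument selection** (`mrchain.instruments`) — genome-wide
  significance screen (p < 5e-8), MAF > 1% filter, greedy p-value-ordered
  LD clumping (r² < 0.001, 10,000 kb window), and F-statistic filtering
  (exclude F < 20) with R² = β²/(β² + N·SE²).
- **Five estimators** (`mrchain.estimators`) — Wald ratio, IVW (fixed and
  multiplicative random effects; the latter is the headline default),
  MR-Egger with intercept test, weighted median, and simple/weighted
  mode, all reported with 95% CI, p, and odds-ratio scale. Median/mode
  SEs come from a seeded parametric bootstrap.
- **Sensitivity cascade** (`mrchain.sensitivity`) — Cochran's Q,
  leave-one-out IVW, and an MR-PRESSO-style residual-simulation test
  (global p, Bonferroni-adjusted per-SNP outliers, outlier-corrected
  estimate, distortion test).
- **SMR + HEIDI** (`mrchain.smr`) — the chi-square(1) SMR test at the top
  QTL SNP and a Monte-Carlo HEIDI test over SNPs in LD (r² in
  [0.05, 0.9], 3–20 SNPs), with the decision rule SMR p < 0.05 and
  HEIDI p > 0.05.
- **Two-step mediation MR** (`mrchain.mediation`) — three univariable MR
  legs (total, exposure→mediator, mediator→outcome), indirect effect
  β₁·β₂ with delta-method SE, proportion mediated, direct effect, and the
  directional-consistency filter on the signs of (β, β₁, β₂).
- **Synthetic data** (`mrchain.simulate`) — multi-trait summary
  statistics over LD blocks with known instrument effects, optional
  (balanced/directional) pleiotropy, exposure→mediator→outcome chains,
  and region-level shared-causal vs linkage scenarios for HEIDI.
- **Pipeline + CLI** (`mrchain.pipeline`, `mrchain.cli`) — TOML-driven
  orchestration of the three stages with deterministic TSV reports and a
  reproducibility manifest.

Note on mediation: β₂ is estimated by *univariable* MR of the mediator on
the outcome (not multivariable MR adjusting for the exposure), mirroring
the two-step design; when the mediator's instruments overlap the
exposure's, the β₂ leg can absorb part of the direct path.

## CLI

```sh
# self-contained synthetic study
mrchain simulate --out-dir sim --seed 3 --n-variants 60 --n-instruments 30 --direct 0.3

# stage-1 screen of one exposure vs one outcome
mrchain mr --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
  --ld-matrix sim/ld_matrix.txt --ld-positions sim/ld_positions.txt \
  --out mr_results.tsv

# two-step mediation
mrchain mediate --exposure sim/exposure.tsv --mediator sim/mediator.tsv \
  --outcome sim/outcome.tsv --ld-matrix sim/ld_matrix.txt \
  --ld-positions sim/ld_positions.txt --out mediation.tsv

# full three-stage pipeline from a TOML config
mrchain pipeline --config run.toml --out-dir results
```

A minimal self-contained pipeline config:

```toml
[run]
stages = ["mr", "smr", "mediate_up", "mediate_down"]
seed = 7

[simulate]
n_variants = 120
n_instruments = 40
n_blocks = 120
effect_sd = 0.03
n_med_instruments = 40
med_effect_sd = 0.06
beta1_true = 0.4
beta2_true = 0.3
direct_true = 0.08
shared_causal = true
```

Thresholds (`p_threshold`, `clump_r2`, `clump_kb`, `f_min`, `maf_min`,
`alpha`, ...) live in a `[thresholds]` table and on the CLI
(`--pval-threshold`, `--clump-r2`, `--clump-kb`, `--f-min`, `--maf-min`).
Real data runs replace `[simulate]` with an `[inputs]` table of file
paths and per-file column maps (arbitrary source headers are mappable to
the canonical `SNP CHR POS EA OA EAF BETA SE P N`).

## File formats

- Summary statistics: tab-separated, header `SNP CHR POS EA OA EAF BETA
  SE P N`; empty `EAF`/`N` fields mean missing (never zero).
- LD matrix: first line whitespace-separated rsids, then the signed
  correlation matrix rows; companion two-column `rsid position` file.
  A long-form `rsid_a rsid_b r` triple format is also accepted.
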