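# methylscreen

Toolkit for quality control and downstream analysis of enzymatically
converted (C→T) cfDNA methylation sequencing:

- **conversion_sim** — simulates post-conversion reads from control and
  cfDNA-like molecules with explicit *sporadic* (per-site) and *clustered*
  (per-molecule) conversion-failure modes, with full per-read ground truth.
- **context_qc** — calls per-read methylation contexts (CpG / CHG / CHH)
  against the reference, counts unconverted CH sites per read, deduplicates,
  and removes incompletely converted reads (≥ 3 unconverted CHs by default).
- **methylquant** — per-CpG/per-CH methylation aggregation, hypo/hyper
  control-site classification, conversion-efficiency estimation, and
  incomplete-conversion hotspot detection (residual CpG signal supported by
  nearby CH signal).
- **panel_design** — differential expression/methylation screens with
  BH-FDR, marker selection (hypermethylated + downregulated, then a blood
  background filter), and the five-probe in-silico-converted capture probe
  designer (original + converted methylated/unmethylated Watson/Crick).
- **cohort_sim** — synthetic three-class plasma cohorts (normal / liver
  disease / cancer with stages) under a tumour-fraction mixture model with
  beta-binomial sampling noise and simulated AFP / PIVKA-II serology.
- **screen_model** — the two-layer stacked classifier: gradient-boosting
  HN (cancer vs normal, RFECV feature selection) and HL (cancer vs liver
  disease, importance > 0 selection) models combined by an L2-penalised
  logistic regression producing the t-score; strict out-of-fold stacking
  with a built-in leakage audit.
- **metrics_report** — confusion metrics, normal-approximation proportion
  CIs, rank-based AUC with DeLong CIs, subgroup positive-rate tables,
  Student's t group tests, and fragment-length profiling (modal length,
  10-bp sub-peak periodicity).
- **io_cli** — FASTA/SAM readers and writers, bedGraph + per-cytosine
  reports, TSV sample sheets/matrices, YAML config with strict key
  validation, and the `methylscreen` command-line interface.

## CLI

```sh
methylscreen --help
methylscreen simulate-control --fasta refs.fa --out-dir sim \
    --cpg-methylated pUC19 --n-fragments 50000 --seed 7
methylscreen qc-filter --sam sim/reads.sam --fasta refs.fa --out-dir qc
methylscreen quantify  --sam qc/kept.sam  --fasta refs.fa --out-dir quant
methylscreen hotspots  --cytosine-report quant/cytosine_report.tsv --out hotspots.tsv
methylscreen simulate-cohort --out-dir cohort --seed 11
methylscreen train   --cohort-dir cohort --out-dir model
methylscreen predict --model model/stack_model --betas cohort/betas_test.tsv --out preds.tsv
methylscreen report  --predictions preds.tsv --samples cohort/samples_test.tsv --out report.json
methylscreen design-probes --fasta refs.fa --bed cpgs.bed --out probes.fa
methylscreen select-markers --expr expr.tsv --beta beta.tsv --groups groups.tsv \
    --mapping map.tsv --blood-beta blood.tsv --out markers.tsv
```

All commands accept `--config config.yaml` (see
`methylscreen.io_cli.config.PipelineConfig`); unknown keys are rejected.
Every run logs the package version, seed and a config hash.

## Conventions

Coordinates are 0-based half-open internally and in BED/bedGraph; the
per-cytosine report is 1-based. Reads are stored in forward-reference
orientation with an origin-strand flag (`+` Watson, `-` Crick); Crick-origin
conversion appears as G→A in forward coordinates. Call-string symbols follow
the de-facto methylation-call-tag convention: `Z/z` CpG, `X/x` CHG, `H/h`
CHH (uppercase = unconverted/methylated), `.` = no call.
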