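# pathherit

Pathway association, multilevel regional heritability, and polygenic risk
profiling for case/control traits — with a synthetic-cohort generator so the
whole pipeline is testable end to end without external data.

The pipeline has two analysis stages plus a risk-profiling stage:

1. **Stage 1 — pathway association.** Either a genotype-based engine
   (gene eigenSNPs in a ridge-penalized logistic regression, tested by
   phenotype permutation) or a summary-statistic engine (per-gene minimum
   SNP p, confounder-corrected by gene size, then 95th-percentile
   enrichment against random gene sets). Benjamini–Hochberg FDR across
   pathways.
2. **Stage 2 — regional heritability.** For each stage-1-significant
   pathway, the SNP panel is partitioned into pathway vs. remainder and
   both genomic relationship matrices (GRMs) are fitted jointly by
   AI-REML; the pathway component is tested with a boundary-corrected
   likelihood-ratio test (0.5·χ²₀ + 0.5·χ²₁) and, optionally, a
   circular-permutation empirical null. Signals are narrowed to gene-level
   fits and fixed-SNP-count block scans.
3. **PRS profiling.** Risk scores weighted by discovery log odds ratios
   under p-value cutoffs, with optional greedy LD clumping; evaluated as a
   fixed effect (logistic regression, Nagelkerke ΔR², Mann–Whitney AUC)
   and as a random effect via a same-PRS-bin indicator covariance fitted
   by REML, alone or jointly with a GRM.

## Package layout

| module | contents |
| --- | --- |
| `pathherit.synthetic` | LD-blocked genotype simulation, liability-threshold phenotypes with a designated causal pathway, ascertained sampling, discovery summary statistics |
| `pathherit.io` | PLINK-1 bed/bim/fam (bit-exact 2-bit codec), dosage TSV, GMT, gene tables, GCTA-style text GRMs; SNP QC, SNP→gene mapping, relatedness pruning |
| `pathherit.pathway` | both stage-1 engines, BH-FDR, Bonferroni |
| `pathherit.vc` | GRM construction, multi-matrix AI-REML (EM warm-up, step-halving ascent), boundary LRT, observed↔liability scale conversion |
| `pathherit.regional` | pathway partitions, two-GRM regional fits, block scans, circular-permutation nulls |
| `pathherit.prs` | clumping, scoring, logistic/AUC evaluation, PRS-bin-matrix LMM |
| `pathherit.pipeline` / `pathherit.cli` | orchestration, report tables, `pathherit` CLI |

## CLI

All verbs read a single YAML config (see `tests/test_pipeline.py` for a
complete example) and write TSV tables plus a run log:

```sh
pathherit simulate --config cfg.yaml --out simdir   # write synthetic cohort
pathherit stage1   --config cfg.yaml --out outdir   # pathway analysis
pathherit stage2   --config cfg.yaml --out outdir   # + gated regional fits
pathherit prs      --config cfg.yaml --out outdir   # risk profiling only
pathherit all      --config cfg.yaml --out outdir   # full pipeline
pathherit report   --indir outdir                   # digest of a report dir
```

The config's `simulate:` block generates inputs in-memory; omit it and
supply `genotypes_path` (PLINK prefix or dosage TSV), `genes_path`,
`gmt_path`, `phenotype_path`, and optionally `summary_path` to run on real
files. Identical config + seed yields byte-identical reports.

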