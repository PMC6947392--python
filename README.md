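# brushmeth

Targeted bisulfite-amplicon DNA-methylation analysis for oral-brushing
samples: from per-sample FASTQ reads to per-CpG methylation ratios, to a
linear-discriminant CpG score with a fixed positivity threshold
(1.0615547), to survival stratification of a treated cohort. A
synthetic-data layer generates amplicon panels, class-conditional
methylation profiles, bisulfite reads and follow-up cohorts so the whole
pipeline runs fully offline.

## Modules

- `brushmeth.synthdata` — panel generation (default 13 genes / 243 CpGs),
  Beta-distributed per-CpG methylation profiles, bisulfite read simulation
  (imperfect conversion, substitution errors, truth-tagged read ids) and
  cohort simulation with configurable relapse hazard ratios.
- `brushmeth.methcall` — read-level Q30 mean-quality filter, in-silico
  C→T converted-reference alignment (ungapped, CpG-aware mismatch
  counting, reverse-complement orientation), per-CpG ratio calling
  #C/(#C+#T) with a coverage floor, and duplicate-run reliability (OLS R²).
- `brushmeth.scoring` — per-CpG ROC/AUC ranking, two-class LDA score
  (`S = Σ cᵢ·mᵢ + b`), Youden-J threshold selection or the fixed published
  threshold, sample classification and cohort positivity summaries.
- `brushmeth.prognosis` — Pearson chi-square contingency analysis, one-way
  ANOVA, Kaplan–Meier estimation, log-rank test, Cox proportional hazards
  (Newton–Raphson, Efron ties, Wald CIs), bidirectional stepwise selection
  with a univariate p<0.25 screen, and a global Schoenfeld PH test.
- `brushmeth.cli` — the `brushmeth` command tying the stages together.

## CLI

```bash
# end-to-end on synthetic data
brushmeth run-all --out runs/demo --seed 1

# or stage by stage
brushmeth simulate --out runs/sim --seed 1
brushmeth call --panel-fasta runs/sim/panel.fasta --panel-cpgs runs/sim/panel_cpgs.tsv \
    --reads-dir runs/sim/reads --out runs/call
brushmeth train --matrix runs/call/matrix.tsv --coverage runs/call/coverage.tsv \
    --labels runs/sim/training_labels.csv --out runs/train
brushmeth score --matrix runs/call/matrix.tsv --coverage runs/call/coverage.tsv \
    --model runs/train/model.json --out runs/score
brushmeth survive --cohort runs/sim/cohort.csv --scores runs/score/scores.csv \
    --out runs/survive
```

Every command writes a manifest (parameters + output checksums); reruns
with the same seed are byte-identical. Formats are plain text throughout:
FASTA + tab-separated CpG sidecar for panels, 4-line FASTQ (optionally
gzipped) for reads, TSV matrices with `NA` for missing ratios, JSON for
models/QC/survival reports, CSV for cohorts and classifications.

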