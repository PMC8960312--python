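# cnvscore

Point-based classification of copy-number variants (CNVs) and
inter-laboratory concordance analysis.

`cnvscore` implements the semiquantitative, five-tier (P / LP / VUS / LB / B)
point-based scoring framework used in clinical CNV interpretation as a fully
data-driven rubric engine, together with:

* **genome model** — 1-based inclusive interval arithmetic, CNV calls,
  gene/region annotation with curated-vs-uncurated dosage-sensitivity gating;
* **rubric engine** — editable YAML scoring tables (loss and gain), point
  validation, exclusive-category enforcement, optional section caps,
  threshold-based five-tier classification;
* **auto evidence** — deterministic section 1–3 assignment from annotation
  (genomic content, established HI/TS and benign regions, gene counts with
  optional gene-family collapsing); sections 4–5 are worksheet-only;
* **concordance** — a conflict-severity taxonomy over multi-laboratory
  classification matrices (complete / confidence difference / management
  impact / return-of-results impact), subset breakdowns, pooled rates with
  round-half-up integer percentages, and 2×2 Pearson chi-square comparisons;
* **audit** — re-review bookkeeping: initial vs final discordance patterns,
  resolution tabulation, and reason-tag bucketing by rubric section;
* **simulator** — seeded synthetic annotation, CNV panels, and
  multi-laboratory evidence application with injectable error modes
  (content inversion, uncurated-region misuse, 2J/2K phenotype swaps,
  gene-family collapsing, section-4 weight perturbation/dropout).

The package ships reference data from a published nine-laboratory CNV
classification comparison (an 83-record re-review panel and the study's
concordance tallies) used as worked examples and acceptance anchors.

## CLI

The `cnvscore` command has five subcommands (exit 0 on success, 2 on any
validation error; rubric checksums and seeds are logged to stderr):

```sh
# score CNVs from annotation plus manual worksheets
cnvscore classify --cnvs panel.tsv --genes genes.bed --regions regions.tsv \
    --worksheet evidence.tsv --out report.tsv

# worksheet-only scoring
cnvscore score --cnvs panel.tsv --worksheet evidence.tsv --out report.tsv

# concordance summary of a CNV x laboratory matrix, with a chi-square check
cnvscore concord --matrix matrix.tsv --by dosage_type \
    --compare 41 234 177 234 --out summary.json

# tabulate re-review records (initial vs final patterns, reason buckets)
cnvscore audit --records records.tsv --reasons --out audit.tsv

# seeded simulation: panel + truth worksheets + laboratory matrix
cnvscore simulate --seed 7 --n-cnvs 234 --n-labs 9 \
    --error-rate S2_PHENOTYPE_2J_2K=0.3 --out-prefix scratch/sim
```

Formats: TSV tables (CNVs, regions, worksheets, matrices, review records),
BED or GFF3 gene tracks, read-only structural-variant VCF (SVTYPE DEL/DUP),
YAML rubric configs, JSON summaries. Coordinates are 1-based inclusive
internally; BED is converted at the boundary.

## Customizing the rubric

The shipped tables (`src/cnvscore/data/*_rubric.yaml`) encode the 2020
ACMG/ClinGen technical-standard defaults. Pass `--loss-rubric` /
`--gain-rubric` (or `load_rubric(dtype, path)`) to substitute any rubric with
the same schema: categories with code/section/default/min/max, five-tier
thresholds, gene-count bins, exclusive groups, and optional section caps.
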