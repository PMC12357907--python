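# oligomorph

Quantitative morphometry of multi-channel fluorescence micrographs of
oligodendroglial cultures, with the hierarchical statistics needed for
two-group cohorts of donor cell lines.

The package implements the full analysis chain:

- **synthetic** — ground-truthed scene generator (DAPI nuclei, compact O4
  cells, branched MBP cells with known process trees, DAPI→MBP bleed-through,
  vignetting, shot/read noise) and a nested cohort-table simulator.
- **preprocess** — 8-bit conversion, pseudo-flat-field correction, median
  smoothing, sliding-paraboloid background subtraction, contrast enhancement,
  with per-channel routing.
- **segment** — Huang fuzzy-entropy thresholding (exhaustive `huang` and
  coarse-to-fine `huang2`), binary cleanup (erode/open/dilate/watershed), ROI
  extraction with solidity, and the bleed-through correction filters
  (solidity < 0.7, overlap with DAPI ROIs < 60%).
- **morphometrics** — percent marker-positive cells, average cell size, and
  branch-length / junction-number readouts via two backends: a sub-pixel
  Hessian ridge detector and topological skeletonization with branch-graph
  analysis.
- **stats** — transform-to-normality selection (Yeo-Johnson, Box-Cox,
  orderNorm, sqrt(x+a), asinh), Shapiro/Levene/Box's-M diagnostics,
  mixed-effects ANOVA (group fixed effect, donor-line random intercept, REML),
  line-mean t-tests with Cohen's d, and the eigenvalue-based effective number
  of tests (simpleM) for multiplicity control.
- **pipeline/CLI** — configured, seeded, logged orchestration of all stages.

## CLI

```sh
oligomorph simulate --out table.csv --n-lines 7 --n-fov 10 --group-effect 0.05 --seed 1
oligomorph analyze --outdir out/ --seed 7          # simulated cohort by default
oligomorph analyze --config run.yaml --outdir out/ # YAML config / image manifest
oligomorph stats table.csv --out stats.json
oligomorph report stats.json --out report.md
oligomorph demo --outdir demo_out --seed 0         # paired effect-vs-null study
```

`analyze` consumes either a simulation design or a CSV manifest with columns
`path,group,line,fov,channel` (one row per single-channel TIFF). Outputs:
`measurements.csv`, `measurements_tidy.csv`, `stats.json`, `config.json`.
Exit codes: 0 success, 2 config validation error, 3 partial run (fields
skipped with logged reasons and missing-value records).

All defaults encode the published analysis choices where stated (Huang2 on
DAPI/MBP, Huang on O4, DAPI binary ops erode/open/dilate/watershed, O4
erode/open, solidity and overlap cut-offs, α = 0.05); unstated constants are
explicit config values.

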