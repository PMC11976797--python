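# vepbench

Benchmarking of variant-effect predictors against a cell-based functional
assay, plus ACMG/AMP point-based clinical variant classification.

The pipeline:

1. **assay** — normalizes raw per-replicate reporter readings to
   relative-wildtype (R-WT) activity, `(var − EV) / (WT − EV)` within each
   (biological, technical) replicate pair; averages replicates into a
   per-variant ground truth; labels variants loss-of-function (LoF) when
   mean R-WT < 0.6; builds the evaluation set by excluding variants with a
   non-conflicting definitive clinical assertion.
2. **predictions** — ingests predictor score tables with a declared
   orientation (activity-scale or pathogenicity-scale), maps them onto
   common regression and classification views, and mean-imputes missing
   scores on the evaluation set.
3. **metrics** — Pearson correlation, Kendall tau-b and ROC AUC with
   1000-sample paired bootstrap confidence intervals (stratified by class
   for AUC), average-rank predictor ranking (two-stage team ranking
   supported), one-sided exact binomial head-to-head tests on shared
   bootstrap draws, and predictor-vs-predictor correlation matrices.
4. **expmax** — a stochastic replicate-resampling predictor (uniform
   biological replicate, then uniform technical value) whose averaged
   performance over 1000 realizations quantifies assay consistency and
   upper-bounds predictor performance.
5. **difficulty** — per-variant FPR/FNR difficulty profiles across
   competitive predictors (best per team, AUC > 0.8).
6. **acmg** — point-based evidence combination (PS3/BS3, PM2/BS1,
   PP3/BP4 via calibrated score intervals, PM5 from co-located pathogenic
   variants) with category mapping P / LP / VUS-high/mid/low / LB / B.
7. **synthetic** — generators for structurally realistic assay replicate
   tables and predictor score sets (tunable noise, target rank
   correlation, missingness), so the whole pipeline is testable offline.

Packaged fixtures (`vepbench/data/`) carry the 28-variant activity and
classification tables used by the golden tests; they are checksummed at
load time.

## CLI

```sh
vepbench simulate --seed 1 --out sim/               # synthetic bundle
vepbench ground-truth --replicates sim/replicates.tsv --out gt.tsv
vepbench evaluate --manifest sim/manifest.yaml --truth gt.tsv --out eval/
vepbench experimental-max --replicates sim/replicates.tsv --eval-mode all --out expmax.tsv
vepbench difficulty --manifest predictors.yaml --out diff/
vepbench classify --out classification.tsv          # packaged fixture inputs
vepbench run-all --config run.yaml                  # end-to-end, seeded
```

The predictor manifest is a YAML list of
`{name, orientation: activity|pathogenicity, role: participant|baseline,
team, scores: <tsv path>}` entries; score files are two-column
(variant, score) tables with blank/NA for missing.

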